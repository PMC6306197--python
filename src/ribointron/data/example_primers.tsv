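# Placeholder primer set for demonstrations and tests only.
# These are NOT a published primer set; supply your own primer table
# (name, orientation, sequence 5'->3', critical_window) for real audits.
name	orientation	sequence	critical_window
V4f-demo	forward	CCAGCASCYGCGGTAATTCC	3
V4r-demo	reverse	ACTTTCGTTCTTGATYRA	3
V9f-demo	forward	TTGTACACACCGCCC	3
V9r-demo	reverse	CCTTCYGCAGGTTCACCTAC	3
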