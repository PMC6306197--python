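gene	location	family	position	B. jadranum	B. furcatum PMFBA4	B. furcatum Na8A3	B. hyalinum CCMP141	C. sp. Clade Na13C2	C. sp. Clade CDP22	C. circinalis	C. sp. Clade Na17B2	C. sp. Clade Na12A3	C. diversus 1	C. diversus 2	C. seiracanthus	C. rotosporus	C. decipiens Na & MC	C. sp. Clade Na28A1	C. sp. Clade Va7-D2	C. anastomosans	C. vixvisibilis group 1	C. vixvisibilis group 2
18S	1	SP	385-386										132	106+					?			
18S	2	SP	442-443					90+	104		110	107	96	125					?			
18S	3	SP	548-549					?	108										?			
18S	4	GI	549-550	400	221+	399		?			360+	453		547	467	457	425	181+	?			
18S	5	SP	888-889					130			124	110										
18S	6	SP	889-890										121									
18S	7	SP	891-892		115		57+															
18S	8	SP	981-982						?			51+	123						?			
18S	9	SP	989-990					162	?	100	107			160-199					?	123		
18S	10	SP	1011-1012		92+			115	?			96	109	161				124	?			
18S	11	SP	1147-1148		?			112	?		101	94	104	133				141	?			
18S	12	GI	1151-1152		?				?						462-465	505-513			?			
18S	13	SP	1195-1196		?			152	71+	110	100	104	105	121				141	?			
18S	14	SP	1257-1258		?					?	392+								?			
18S	15	SP	1274-1275		?			80	106	?	102			86-96				134	?			342+
18S	16	SP	1414-1415		?			117		106+	99	108	35+	153					?			
18S	17	SP	1612-1613	?	?							98							?			
18S	18	SP	1615-1616	?	?			115	116		118		117	96-97			15		?		154	98-154
18S	19	SP	1760-1761	?	?	?	?	109+	?	?	?	?	91+	91+	?	?	94+	92+	?	73+	?	?
28S	1	SP	758-759					112			108	112-116		115				205+	94-105			
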