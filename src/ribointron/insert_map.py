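"""Insert detection and coordinate mapping in rDNA alignments.

An *insert* (intron candidate) is a maximal run of alignment columns in
which the intron-free reference row is gapped and most other rows are
gapped too.  Each insert is mapped to the pair of reference core
nucleotides flanking it — the "flank pair" (p5, p3 = p5+1), 1-based on the
ungapped reference — which is the coordinate convention used to catalogue
intron locations across taxa.  The module also produces core (insert-free)
alignments and per-taxon summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .seqio import InsertTableFixture, MultipleAlignment, SequenceRecord

__all__ = [
    "InsertRecord",
    "IntronLocation",
    "CoreExtraction",
    "detect_inserts",
    "group_locations",
    "extract_core",
    "tabulate_inserts",
    "insert_report_rows",
]

FAMILIES = ("SP", "GI", "ambiguous", "partial", "partial(SP-like)", "unclassified")


@dataclass
class InsertRecord:
    """One insert observed in one sequence.

    ``col_span`` is a 0-based half-open alignment-column interval;
    ``flank_pair`` the 1-based reference core positions flanking the
    insertion point (p3 = p5 + 1).  ``complete=False`` marks inserts whose
    full extent was not sequenced (span touching an alignment end, a read
    stopping inside the insert, or 'N' fill in the insert residues).
    """

    seq_id: str
    col_span: tuple[int, int]
    flank_pair: tuple[int, int]
    observed_len: int
    complete: bool = True
    family: str = "unclassified"
    taxon: str = ""
    gene: str = "other"

    def __post_init__(self) -> None:
        start, end = self.col_span
        if end <= start:
            raise ValueError(f"empty column span {self.col_span}")
        p5, p3 = self.flank_pair
        if p3 != p5 + 1:
            raise ValueError(
                f"flank pair must be adjacent core positions, got {self.flank_pair}"
            )
        if self.observed_len < 1:
            raise ValueError("observed_len must be >= 1")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def location_label(self) -> str:
        """Flank pair rendered as in printed insert tables, e.g. ``385–386``."""
        return f"{self.flank_pair[0]}–{self.flank_pair[1]}"


@dataclass
class IntronLocation:
    """A cross-taxon insert site, keyed by its reference flank pair."""

    gene: str
    flank_pair: tuple[int, int]
    members: list[str]
    index: int = 0
    family_consensus: str = "unclassified"

    @property
    def location_label(self) -> str:
        return f"{self.flank_pair[0]}–{self.flank_pair[1]}"


@dataclass
class CoreExtraction:
    """Result of removing insert columns from an alignment."""

    core_alignment: MultipleAlignment
    per_seq_core: dict[str, str]
    removed_spans: list[tuple[int, int]] = field(default_factory=list)


def _insert_segment(residues: str, span: tuple[int, int]) -> str:
    return residues[span[0] : span[1]].replace("-", "")


def _is_truncated(residues: str, span: tuple[int, int], n_cols: int, segment: str) -> bool:
    start, end = span
    if start == 0 or end == n_cols:
        return True
    if "N" in segment:
        return True
    # read stopped inside (or started inside) the insert: nothing beyond it
    if residues[end:].count("-") == len(residues) - end:
        return True
    if residues[:start].count("-") == start:
        return True
    return False


def detect_inserts(
    aln: MultipleAlignment,
    reference_id: str,
    presence_max_frac: float = 0.5,
    min_len: int = 1,
    gene: str | None = None,
) -> list[InsertRecord]:
    """Detect inserts relative to an intron-free reference row.

    A column is an *insert column* when the reference row is gapped there
    and the fraction of rows with a residue is at most ``presence_max_frac``
    (inserts are carried by a minority of sequences).  Maximal runs of
    insert columns become spans; each sequence with at least ``min_len``
    residues inside a span yields one :class:`InsertRecord`.  Runs of
    reference gaps touching the alignment ends are treated as frayed
    termini, not inserts.
    """
    try:
        ref = aln[reference_id]
    except KeyError:
        raise ValueError(f"reference id {reference_id!r} not in alignment") from None
    n_rows, n_cols = len(aln), aln.n_cols
    rows = [r.residues for r in aln.records]

    is_insert_col = []
    for j in range(n_cols):
        if ref.residues[j] != "-":
            is_insert_col.append(False)
            continue
        present = sum(1 for row in rows if row[j] != "-")
        is_insert_col.append(present / n_rows <= presence_max_frac)

    # maximal runs of insert columns
    spans: list[tuple[int, int]] = []
    j = 0
    while j < n_cols:
        if is_insert_col[j]:
            k = j
            while k < n_cols and is_insert_col[k]:
                k += 1
            if j == 0 or k == n_cols:
                warnings.warn(
                    f"frayed terminal reference gap run at columns [{j},{k}) excluded"
                )
            else:
                spans.append((j, k))
            j = k
        else:
            if ref.residues[j] == "-":
                warnings.warn(
                    f"reference {reference_id!r} gapped at column {j} outside any "
                    "insert column (possible fraying or shared insert)"
                )
            j += 1

    records: list[InsertRecord] = []
    for start, end in spans:
        p5 = sum(1 for c in ref.residues[:start] if c != "-")
        for rec in aln.records:
            if rec.id == reference_id:
                continue
            segment = _insert_segment(rec.residues, (start, end))
            if len(segment) < max(min_len, 1):
                continue
            records.append(
                InsertRecord(
                    seq_id=rec.id,
                    col_span=(start, end),
                    flank_pair=(p5, p5 + 1),
                    observed_len=len(segment),
                    complete=not _is_truncated(rec.residues, (start, end), n_cols, segment),
                    taxon=rec.taxon,
                    gene=gene or rec.gene,
                )
            )
    return records


def group_locations(inserts: Iterable[InsertRecord], gene: str = "other") -> list[IntronLocation]:
    """Group inserts from one alignment into cross-taxon locations.

    One location per distinct flank pair, ordered by p5 ascending and
    indexed 1..n.  Adjacent flank pairs remain distinct locations.
    """
    by_pair: dict[tuple[int, int], list[InsertRecord]] = {}
    for rec in inserts:
        by_pair.setdefault(rec.flank_pair, []).append(rec)
    locations = []
    for idx, pair in enumerate(sorted(by_pair), start=1):
        members = sorted({r.seq_id for r in by_pair[pair]})
        fams = {r.family for r in by_pair[pair] if r.family != "unclassified"}
        consensus = fams.pop() if len(fams) == 1 else ("ambiguous" if fams else "unclassified")
        locations.append(
            IntronLocation(
                gene=gene, flank_pair=pair, members=members, index=idx,
                family_consensus=consensus,
            )
        )
    return locations


def extract_core(aln: MultipleAlignment, inserts: Sequence[InsertRecord]) -> CoreExtraction:
    """Delete insert-column spans, yielding the core alignment and sequences.

    The removal is invertible: re-inserting each removed segment between
    its flank pair reconstructs every input sequence exactly.
    """
    spans = sorted({rec.col_span for rec in inserts})
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping insert spans [{s1},{e1}) and [{s2},{e2})")
    keep = [True] * aln.n_cols
    for s, e in spans:
        for j in range(s, e):
            keep[j] = False
    core_records = []
    for rec in aln.records:
        residues = "".join(c for c, k in zip(rec.residues, keep) if k)
        core_records.append(replace(rec, residues=residues))
    core_aln = MultipleAlignment(core_records)
    per_seq_core = {r.id: r.ungapped() for r in core_records}
    return CoreExtraction(core_aln, per_seq_core, spans)


def tabulate_inserts(source, gene: str | None = None) -> dict[str, pd.DataFrame]:
    """Summarise an insert catalogue per taxon and per location.

    ``source`` is either an :class:`~ribointron.seqio.InsertTableFixture`
    or an iterable of :class:`InsertRecord` with taxon labels.  Per taxon:
    the number of insert-bearing locations and the summed maximum insert
    length (ranges contribute their upper bound, truncated inserts the
    sequenced length).  Per location: the count of carrying taxa and the
    min/max of complete lengths.
    """
    if isinstance(source, InsertTableFixture):
        entries = [
            (g, loc, taxon, e.min_len, e.max_len, e.complete)
            for (g, loc, taxon), e in source.cells.items()
        ]
        fam = {(r.gene, r.location_index): r.family for r in source.rows}
        pair = {(r.gene, r.location_index): r.flank_pair for r in source.rows}
    else:
        records = list(source)
        locs = group_locations(records, gene=gene or "other")
        loc_index = {l.flank_pair: l.index for l in locs}
        entries = [
            (r.gene, loc_index[r.flank_pair], r.taxon or r.seq_id,
             r.observed_len, r.observed_len, r.complete)
            for r in records
        ]
        fam = {(l.gene, l.index): l.family_consensus for l in locs}
        pair = {(l.gene, l.index): l.flank_pair for l in locs}

    if gene is not None:
        entries = [e for e in entries if e[0] == gene]

    df = pd.DataFrame(
        entries, columns=["gene", "location", "taxon", "min_len", "max_len", "complete"]
    )
    if df.empty:
        per_taxon = pd.DataFrame(columns=["n_inserts", "sum_max_len"])
        per_location = pd.DataFrame(
            columns=["gene", "family", "flank_pair", "n_taxa",
                     "min_complete_len", "max_complete_len"]
        )
        return {"per_taxon": per_taxon, "per_location": per_location}

    # a taxon may have several entries at one location (e.g. polymorphic
    # copies); count the location once, with its maximum length
    per_cell = df.groupby(["gene", "location", "taxon"], as_index=False)["max_len"].max()
    per_taxon = (
        per_cell.groupby("taxon")
        .agg(n_inserts=("location", "count"), sum_max_len=("max_len", "sum"))
        .sort_index()
    )

    rows = []
    for (g, loc), sub in df.groupby(["gene", "location"]):
        comp = sub[sub["complete"]]
        rows.append(
            {
                "gene": g,
                "location": loc,
                "family": fam.get((g, loc), "unclassified"),
                "flank_pair": pair.get((g, loc)),
                "n_taxa": sub["taxon"].nunique(),
                "min_complete_len": int(comp["min_len"].min()) if len(comp) else None,
                "max_complete_len": int(comp["max_len"].max()) if len(comp) else None,
            }
        )
    per_location = pd.DataFrame(rows).set_index("location")
    return {"per_taxon": per_taxon, "per_location": per_location}


def insert_report_rows(inserts: Sequence[InsertRecord], locations: Sequence[IntronLocation]):
    """Flatten inserts into report dicts (the machine-readable catalogue)."""
    idx = {l.flank_pair: l.index for l in locations}
    return [
        {
            "gene": r.gene,
            "location_index": idx.get(r.flank_pair, ""),
            "family": r.family,
            "flank_pair": r.location_label,
            "seq_id": r.seq_id,
            "taxon": r.taxon,
            "observed_len": r.observed_len,
            "complete": r.complete,
        }
        for r in sorted(inserts, key=lambda r: (r.flank_pair, r.seq_id))
    ]
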