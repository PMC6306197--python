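"""Input/output for the formats the pipeline touches.

FASTA (plain and aligned), delimited primer configurations, the packaged
machine-readable insert table, and TSV/JSON report writing.  All sequence
ingest normalises to an uppercase DNA alphabet ('U' -> 'T') so downstream
modules work over a single alphabet.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "MultipleAlignment",
    "PrimerSpec",
    "LengthEntry",
    "InsertTableRow",
    "InsertTableFixture",
    "read_fasta",
    "write_fasta",
    "load_primer_config",
    "load_insert_table",
    "packaged_insert_table",
    "write_report",
]

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
GENES = ("18S", "28S", "other")


@dataclass
class SequenceRecord:
    """One rDNA sequence: identifier, free-text taxon label, gene tag, residues."""

    id: str
    residues: str
    taxon: str = ""
    gene: str = "other"
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if self.gene not in GENES:
            raise ValueError(f"gene must be one of {GENES}, got {self.gene!r}")
        if not self.aligned and "-" in self.residues:
            raise ValueError(f"unaligned sequence {self.id!r} contains gap characters")

    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """An ordered set of equal-length aligned sequences (gap character '-')."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        n = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != n:
                raise ValueError(
                    f"ragged alignment: {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {n}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s): {', '.join(dup)}")
        for j in range(n):
            if all(r.residues[j] == "-" for r in self.records):
                warnings.warn(f"alignment column {j} is all gaps")
                break

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


@dataclass(frozen=True)
class PrimerSpec:
    """A PCR primer as synthesised, written 5'->3'.

    ``critical_window`` is the number of 3'-terminal bases where a template
    mismatch is considered extension-blocking.  Reverse primers are stored
    as written; the matching machinery reverse-complements them.
    """

    name: str
    orientation: str
    sequence: str
    critical_window: int

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"primer {self.name!r}: orientation must be 'forward' or "
                f"'reverse', got {self.orientation!r}"
            )
        if not self.sequence:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        for i, base in enumerate(self.sequence):
            if base not in IUPAC_DNA:
                raise ValueError(
                    f"primer {self.name!r}: non-IUPAC character {base!r} at position {i}"
                )
        if not 1 <= self.critical_window <= len(self.sequence):
            raise ValueError(
                f"primer {self.name!r}: critical_window {self.critical_window} out of "
                f"range [1, {len(self.sequence)}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LengthEntry:
    """One insert-table cell: an observed length or length range.

    ``complete=False`` corresponds to a '+'-suffixed printed value — the
    sequenced part of an insert whose true length is unknown.
    """

    min_len: int
    max_len: int
    complete: bool

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")


@dataclass(frozen=True)
class InsertTableRow:
    location_index: int
    family: str
    flank_pair: tuple[int, int]
    gene: str

    def __post_init__(self) -> None:
        p5, p3 = self.flank_pair
        if p3 <= p5:
            raise ValueError(f"flank pair {self.flank_pair} is not strictly increasing")
        if self.family not in ("SP", "GI"):
            raise ValueError(f"family must be SP or GI, got {self.family!r}")


@dataclass
class InsertTableFixture:
    """Machine-readable insert location table.

    ``rows`` lists the insert locations per gene in alignment order;
    ``cells`` maps ``(gene, location_index, taxon)`` to a :class:`LengthEntry`.
    Cells whose presence is unknown ('?') are absent from ``cells``.
    """

    rows: list[InsertTableRow]
    cells: dict[tuple[str, int, str], LengthEntry]
    taxa: list[str] = field(default_factory=list)

    def locations(self, gene: str) -> list[InsertTableRow]:
        return [r for r in self.rows if r.gene == gene]


def _normalise(residues: str) -> str:
    return residues.upper().replace("U", "T")


def read_fasta(path, aligned: bool = False, gene: str = "other"):
    """Read a FASTA file.

    Header up to the first whitespace becomes the id; the remainder the
    taxon label.  Residues are uppercased and 'U' is normalised to 'T'.
    With ``aligned=True`` an equal-length check is enforced and a
    :class:`MultipleAlignment` is returned; otherwise a list of
    :class:`SequenceRecord`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        taxon = desc[len(rec.id):].strip() if desc.startswith(rec.id) else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalise(str(rec.seq)),
                taxon=taxon,
                gene=gene,
                aligned=aligned,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if aligned:
        return MultipleAlignment(records)
    return records


def write_fasta(records, path) -> None:
    """Write :class:`SequenceRecord` objects (or an alignment) as FASTA."""
    if isinstance(records, MultipleAlignment):
        records = records.records
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id} {rec.taxon}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def load_primer_config(path) -> list[PrimerSpec]:
    """Load a delimited primer table: name, orientation, sequence, critical_window.

    Accepts TSV or CSV (sniffed from the header line).  Reverse primers are
    kept exactly as written 5'->3'.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    required = {"name", "orientation", "sequence", "critical_window"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(
            f"primer config {path} must have columns {sorted(required)}, "
            f"got {reader.fieldnames}"
        )
    primers = []
    for row in reader:
        try:
            window = int(row["critical_window"])
        except ValueError as exc:
            raise ValueError(
                f"primer {row['name']!r}: critical_window {row['critical_window']!r} "
                "is not an integer"
            ) from exc
        primers.append(
            PrimerSpec(
                name=row["name"].strip(),
                orientation=row["orientation"].strip(),
                sequence=_normalise(row["sequence"].strip()),
                critical_window=window,
            )
        )
    if not primers:
        raise ValueError(f"no primers in {path}")
    return primers


def _parse_cell(token: str) -> LengthEntry | None:
    """Parse one insert-table cell token.

    Grammar: '' or '?' -> unknown (None); '123' exact; '123+' sequenced part
    of a longer insert; '123-134' (hyphen or en-dash) length range.
    """
    token = token.strip().strip("*")
    if token in ("", "?"):
        return None
    if token.endswith("+"):
        v = int(token[:-1])
        return LengthEntry(v, v, complete=False)
    for dash in ("–", "-"):
        if dash in token:
            lo, hi = token.split(dash)
            return LengthEntry(int(lo), int(hi), complete=True)
    v = int(token)
    return LengthEntry(v, v, complete=True)


def load_insert_table(path) -> InsertTableFixture:
    """Load a wide-format insert location table.

    Expected columns: gene, location, family, position (``p5-p3``), then one
    column per terminal taxon holding length tokens (see :func:`_parse_cell`).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[:4] != ["gene", "location", "family", "position"]:
        raise ValueError(
            f"insert table {path}: first columns must be "
            f"gene/location/family/position, got {header[:4]}"
        )
    taxa = header[4:]
    rows: list[InsertTableRow] = []
    cells: dict[tuple[str, int, str], LengthEntry] = {}
    seen: set[tuple[str, int]] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        parts += [""] * (len(header) - len(parts))
        gene, loc_s, family, position = (p.strip() for p in parts[:4])
        loc = int(loc_s)
        if (gene, loc) in seen:
            raise ValueError(f"{path}:{lineno}: duplicate location {loc} for {gene}")
        seen.add((gene, loc))
        pos = position.replace("–", "-")
        p5_s, p3_s = pos.split("-")
        row = InsertTableRow(loc, family, (int(p5_s), int(p3_s)), gene)
        rows.append(row)
        for taxon, token in zip(taxa, parts[4:]):
            try:
                entry = _parse_cell(token)
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed cell {token!r} in column {taxon!r}"
                ) from exc
            if entry is not None:
                cells[(gene, loc, taxon)] = entry
    return InsertTableFixture(rows=rows, cells=cells, taxa=taxa)


def packaged_insert_table() -> InsertTableFixture:
    """Load the insert table shipped with the package."""
    ref = resources.files("ribointron").joinpath("data/insert_table.tsv")
    with resources.as_file(ref) as p:
        return load_insert_table(p)


def _row_to_dict(row) -> dict:
    if isinstance(row, Mapping):
        return dict(row)
    if hasattr(row, "__dataclass_fields__"):
        return {f.name: getattr(row, f.name) for f in dc_fields(row)}
    raise TypeError(f"cannot serialise row of type {type(row).__name__}")


def write_report(rows: Iterable, path, format: str = "tsv", columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as TSV (one header row) or a JSON array.

    Column order follows the first record (or ``columns`` when given, which
    also lets an empty row list produce a header-only file); rows may be
    dicts or dataclasses.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    dicts = [_row_to_dict(r) for r in rows]
    if columns is None:
        columns = list(dicts[0]) if dicts else []
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(dicts, indent=1, default=str) + "\n", encoding="utf-8")
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for d in dicts:
            writer.writerow([d.get(c, "") for c in columns])
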