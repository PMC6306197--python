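"""IUPAC primer matching and in-silico amplifiability auditing.

Primers are matched against core (intron-free) sequences with full IUPAC
degeneracy; mismatches are profiled by their offset from the primer's 3'
end, because mismatches under the polymerase's 3' terminus are the ones
that abort extension.  An amplicon audit then combines the two primer
sites of a pair with the sequence's intron annotations: an intron whose
insertion point falls inside a primer's annealing site disrupts that
primer, and introns between the sites inflate the amplicon beyond its
core length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .insert_map import InsertRecord
from .intron_grammar import IUPAC_SETS
from .seqio import PrimerSpec, SequenceRecord

__all__ = [
    "PrimerHit",
    "AmpliconStatus",
    "reverse_complement",
    "find_primer_site",
    "flag_critical",
    "audit_amplicon",
    "extract_region",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PrimerHit:
    """Best-scoring binding site of one primer on one core sequence.

    ``target_interval`` is 1-based closed, on the forward strand of the
    core.  ``mismatch_offsets`` count from the primer's 3' end (0 = the
    terminal base); ``critical`` flags any mismatch within the primer's
    critical window.
    """

    primer_name: str
    seq_id: str
    target_interval: tuple[int, int]
    n_mismatch: int
    mismatch_offsets: tuple[int, ...]
    critical: bool

    def __post_init__(self) -> None:
        if self.n_mismatch != len(self.mismatch_offsets):
            raise ValueError("n_mismatch inconsistent with mismatch_offsets")


@dataclass
class AmpliconStatus:
    """Amplifiability verdict for one sequence under one primer pair."""

    seq_id: str
    status: str  # amplifiable | critical_mismatch | primer_disrupted | region_incomplete
    amplicon_core_len: int = 0
    amplicon_total_len: int = 0
    disrupting_locations: list[tuple[int, int]] = field(default_factory=list)
    fwd_hit: PrimerHit | None = None
    rev_hit: PrimerHit | None = None


def _mismatch_offsets(scan_seq: str, window: str, three_prime_left: bool) -> list[int]:
    """Offsets (from the primer 3' end) of mismatched positions."""
    L = len(scan_seq)
    offsets = []
    for i, (p, w) in enumerate(zip(scan_seq, window)):
        if w == "N" or p == "N":  # unknown target base: lenient
            ok = True
        else:
            ok = w in IUPAC_SETS[p]
        if not ok:
            offsets.append(i if three_prime_left else L - 1 - i)
    return sorted(offsets)


def find_primer_site(
    core: str, primer: PrimerSpec, seq_id: str = ""
) -> PrimerHit:
    """Best binding site of a primer on an ungapped core sequence.

    Reverse primers are reverse-complemented before scanning, so the
    returned interval is always on the forward strand.  All offsets are
    scanned; the minimal-mismatch site wins, ties going to the smallest
    start coordinate.
    """
    L = len(primer)
    if L > len(core):
        raise ValueError(
            f"primer {primer.name!r} ({L} nt) longer than core ({len(core)} nt)"
        )
    reverse = primer.orientation == "reverse"
    scan_seq = reverse_complement(primer.sequence) if reverse else primer.sequence
    best: tuple[int, int, list[int]] | None = None  # (n_mismatch, start, offsets)
    for start in range(len(core) - L + 1):
        window = core[start : start + L]
        offsets = _mismatch_offsets(scan_seq, window, three_prime_left=reverse)
        if best is None or len(offsets) < best[0]:
            best = (len(offsets), start, offsets)
            if best[0] == 0:
                break
    n_mm, start, offsets = best
    return PrimerHit(
        primer_name=primer.name,
        seq_id=seq_id,
        target_interval=(start + 1, start + L),
        n_mismatch=n_mm,
        mismatch_offsets=tuple(offsets),
        critical=any(o < primer.critical_window for o in offsets),
    )


def flag_critical(hit: PrimerHit, primer: PrimerSpec) -> bool:
    """True iff any mismatch falls within the primer's 3'-end critical window."""
    return any(o < primer.critical_window for o in hit.mismatch_offsets)


def _inside(p5: int, interval: tuple[int, int]) -> bool:
    # insertion point between core positions p5/p5+1 sits strictly inside
    # [a, b] iff both flanking bases are within the annealing site
    a, b = interval
    return a <= p5 <= b - 1


def audit_amplicon(
    seq: SequenceRecord | str,
    inserts: Sequence[InsertRecord],
    fwd: PrimerSpec,
    rev: PrimerSpec,
    max_mismatch: int = 2,
    incomplete_mismatch_threshold: int = 6,
) -> AmpliconStatus:
    """Classify one core sequence's amplifiability for a primer pair.

    ``inserts`` are the sequence's intron annotations in core coordinates
    (flank pairs).  Status precedence: region_incomplete (a primer target
    is effectively absent from the core, e.g. a truncated 3' end) >
    primer_disrupted (an intron insertion point inside a primer site) >
    critical_mismatch (a 3'-critical mismatch, or more than
    ``max_mismatch`` mismatches in either primer) > amplifiable.
    """
    if isinstance(seq, SequenceRecord):
        seq_id, core = seq.id, seq.ungapped()
    else:
        seq_id, core = "", seq
    fwd_hit = find_primer_site(core, fwd, seq_id)
    rev_hit = find_primer_site(core, rev, seq_id)

    if (
        fwd_hit.n_mismatch > incomplete_mismatch_threshold
        or rev_hit.n_mismatch > incomplete_mismatch_threshold
    ):
        return AmpliconStatus(seq_id, "region_incomplete", fwd_hit=fwd_hit, rev_hit=rev_hit)

    if rev_hit.target_interval[0] <= fwd_hit.target_interval[1]:
        raise ValueError(
            f"{seq_id or 'sequence'}: reverse primer site {rev_hit.target_interval} "
            f"not downstream of forward site {fwd_hit.target_interval}"
        )

    mine = [r for r in inserts if not isinstance(seq, SequenceRecord) or r.seq_id == seq_id]
    disrupting = sorted(
        {
            r.flank_pair
            for r in mine
            if _inside(r.flank_pair[0], fwd_hit.target_interval)
            or _inside(r.flank_pair[0], rev_hit.target_interval)
        }
    )
    core_len = rev_hit.target_interval[1] - fwd_hit.target_interval[0] + 1
    between = [
        r
        for r in mine
        if fwd_hit.target_interval[1] <= r.flank_pair[0] <= rev_hit.target_interval[0] - 1
    ]
    total_len = core_len + sum(r.observed_len for r in between)

    if disrupting:
        status = "primer_disrupted"
    elif (
        fwd_hit.critical
        or rev_hit.critical
        or fwd_hit.n_mismatch > max_mismatch
        or rev_hit.n_mismatch > max_mismatch
    ):
        status = "critical_mismatch"
    else:
        status = "amplifiable"
    return AmpliconStatus(
        seq_id=seq_id,
        status=status,
        amplicon_core_len=core_len,
        amplicon_total_len=total_len,
        disrupting_locations=list(disrupting),
        fwd_hit=fwd_hit,
        rev_hit=rev_hit,
    )


def extract_region(
    core: str,
    fwd_hit: PrimerHit,
    rev_hit: PrimerHit,
    include_primers: bool = False,
) -> str:
    """Marker region between two primer sites on a core sequence.

    By default the substring strictly between the two target intervals
    (primer positions excluded); introns are already absent because the
    input is a core sequence.
    """
    if rev_hit.target_interval[0] <= fwd_hit.target_interval[1]:
        raise ValueError("reverse primer site not downstream of forward site")
    if include_primers:
        region = core[fwd_hit.target_interval[0] - 1 : rev_hit.target_interval[1]]
    else:
        region = core[fwd_hit.target_interval[1] : rev_hit.target_interval[0] - 1]
    if not region:
        raise ValueError("empty region between primer sites")
    return region
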