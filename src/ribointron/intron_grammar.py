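"""Splice-site grammar scanning, intron classification, and NJ phylograms.

Spliceosomal introns in these rDNA genes follow a compact grammar: a
5' donor matching the degenerate hexamer GTDHNN (usually GTAAGT), a
variable interior, a branch-site pentamer YTRAC (commonly YTAAC), a
pyrimidine-rich (CT-rich) tract, and a 3' acceptor pentamer YNHAG
(usually YAYAG); in the 28S the terminal hexamer additionally matches
YTAMAG (mostly TTAAAG).  Long group IC1 introns lack this grammar and
instead show conserved structural blocks separated by unalignable
regions; those blocks are extracted and compared by p-distance and
neighbor-joining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

from .insert_map import InsertRecord

__all__ = [
    "IUPAC_SETS",
    "GrammarParams",
    "SpliceosomalFeatures",
    "match_iupac",
    "pyrimidine_fraction",
    "scan_spliceosomal",
    "classify_insert",
    "extract_conserved_blocks",
    "p_distance",
    "distance_matrix",
    "nj_tree",
]

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

DONOR = "GTDHNN"
BRANCH = "YTRAC"
ACCEPTOR_18S = "YNHAG"
ACCEPTOR_28S_HEX = "YTAMAG"


def match_iupac(pattern: str, window: str, lenient_n: bool = False) -> bool:
    """True iff each ``window`` base is allowed by the IUPAC ``pattern`` base.

    An 'N' in the window (unknown base) matches only pattern 'N' by default;
    with ``lenient_n=True`` it matches anything.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for p, w in zip(pattern, window):
        allowed = IUPAC_SETS[p]
        if w == "N":
            if lenient_n or p == "N":
                continue
            return False
        if w not in allowed:
            return False
    return True


def pyrimidine_fraction(segment: str) -> float:
    """Fraction of C/T bases in a segment."""
    if not segment:
        raise ValueError("empty segment")
    return (segment.count("C") + segment.count("T")) / len(segment)


@dataclass(frozen=True)
class GrammarParams:
    """Tunable thresholds of the spliceosomal splice-site grammar."""

    donor: str = DONOR
    branch: str = BRANCH
    acceptor: str = ACCEPTOR_18S
    acceptor_28s: str = ACCEPTOR_28S_HEX
    ct_window: int = 10          # nt; window tested for pyrimidine richness
    ct_min_frac: float = 0.6     # minimum C+T fraction in that window
    min_len: int = 25            # shortest insert the grammar can span
    gi_min_len: int = 350        # length threshold for group-I candidacy
    lenient_n: bool = False


@dataclass
class SpliceosomalFeatures:
    """Grammar features located in one insert (offsets 0-based)."""

    donor: tuple[int, str]
    branch: tuple[int, str]
    ct_tract: tuple[tuple[int, int], float]
    acceptor: tuple[int, str]
    acceptor_28s_match: bool | None = None


def scan_spliceosomal(
    insert: str, gene: str = "18S", params: GrammarParams = GrammarParams()
) -> SpliceosomalFeatures | None:
    """Locate the spliceosomal grammar in an insert; None when absent.

    Requires the donor hexamer at offset 0, the acceptor pentamer flush with
    the 3' terminus, a branch pentamer between them, and a pyrimidine-rich
    window between branch and acceptor.  Among branch candidates the 3'-most
    one with a qualifying CT window downstream is chosen.
    """
    n = len(insert)
    if n < params.min_len:
        return None
    d, b, a = len(params.donor), len(params.branch), len(params.acceptor)
    if not match_iupac(params.donor, insert[:d], params.lenient_n):
        return None
    acc_off = n - a
    if not match_iupac(params.acceptor, insert[acc_off:], params.lenient_n):
        return None

    w = params.ct_window

    def best_ct_window(lo: int) -> tuple[tuple[int, int], float] | None:
        # best = max pyrimidine fraction, leftmost on ties, within [lo, acc_off)
        best = None
        for s in range(lo, acc_off - w + 1):
            frac = pyrimidine_fraction(insert[s : s + w])
            if frac >= params.ct_min_frac and (best is None or frac > best[1]):
                best = ((s, s + w), frac)
        return best

    # 3'-most branch candidate leaving room for a CT window before the acceptor
    for off in range(acc_off - b - w, d - 1, -1):
        if not match_iupac(params.branch, insert[off : off + b], params.lenient_n):
            continue
        ct = best_ct_window(off + b)
        if ct is None:
            continue
        features = SpliceosomalFeatures(
            donor=(0, insert[:d]),
            branch=(off, insert[off : off + b]),
            ct_tract=ct,
            acceptor=(acc_off, insert[acc_off:]),
        )
        if gene == "28S":
            hex_off = n - len(params.acceptor_28s)
            features.acceptor_28s_match = match_iupac(
                params.acceptor_28s, insert[hex_off:], params.lenient_n
            )
        return features
    return None


def classify_insert(
    rec: InsertRecord | None,
    sequence: str,
    gene: str = "18S",
    params: GrammarParams = GrammarParams(),
) -> str:
    """Assign an insert to a family.

    Complete inserts: SP when the full grammar is present; otherwise
    "ambiguous" with a possible-nested-SP note when a spliceosomal donor
    opens an insert longer than 300 nt; otherwise GI when the insert
    reaches group-I length (default 350 nt, below the shortest complete
    group-I insert observed in these genes, 399 nt); otherwise ambiguous.
    Truncated inserts are "partial", or "partial(SP-like)" when their
    available 5' end shows the donor.
    """
    if not sequence:
        raise ValueError("empty insert sequence")
    complete = rec.complete if rec is not None else True
    d = len(params.donor)
    has_donor = len(sequence) >= d and match_iupac(
        params.donor, sequence[:d], params.lenient_n
    )
    if not complete:
        return "partial(SP-like)" if has_donor else "partial"
    if scan_spliceosomal(sequence, gene=gene, params=params) is not None:
        return "SP"
    if has_donor and len(sequence) > 300:
        return "ambiguous"  # possible SP nested inside another SP
    if len(sequence) >= params.gi_min_len:
        return "GI"
    return "ambiguous"


def _column_identity(column: Sequence[str]) -> float | None:
    """Mean pairwise identity of a column over pairs with both bases present."""
    bases = [c for c in column if c not in "-N"]
    if len(bases) < 2:
        return None
    pairs = matches = 0
    for x, y in combinations(bases, 2):
        pairs += 1
        matches += x == y
    return matches / pairs


def extract_conserved_blocks(
    aligned: dict[str, str] | Sequence[tuple[str, str]],
    window: int = 10,
    min_identity: float = 0.7,
) -> dict[str, str]:
    """Extract conserved blocks from aligned group-I insert sequences.

    Column identity is smoothed with a centred sliding window of
    ``window`` columns; maximal runs of columns whose smoothed identity
    reaches ``min_identity`` are retained (gap-only columns dropped) and
    concatenated per sequence.
    """
    items = list(aligned.items()) if isinstance(aligned, dict) else list(aligned)
    if len(items) < 2:
        raise ValueError("need at least 2 aligned sequences")
    ids = [i for i, _ in items]
    seqs = [s for _, s in items]
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("aligned sequences must have equal length")

    ident = np.array(
        [
            (v if (v := _column_identity([s[j] for s in seqs])) is not None else 0.0)
            for j in range(n)
        ]
    )
    half = window // 2
    smoothed = np.empty(n)
    for j in range(n):
        lo, hi = max(0, j - half), min(n, j + half + 1)
        smoothed[j] = ident[lo:hi].mean()
    keep = smoothed >= min_identity

    out = {}
    for sid, s in zip(ids, seqs):
        kept = "".join(
            c for c, k, col_gap in zip(
                s, keep, (all(t[j] == "-" for t in seqs) for j in range(n))
            )
            if k and not col_gap
        )
        out[sid] = kept.replace("-", "")
    return out


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatched sites, skipping '-' and 'N' in either sequence."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        mismatches += x != y
    if compared == 0:
        raise ValueError("no comparable sites")
    return mismatches / compared


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor corrected distance; infinite saturation raises."""
    p = p_distance(a, b)
    if p >= 0.75:
        raise ValueError(f"p-distance {p:.3f} >= 0.75: JC correction undefined")
    return -0.75 * np.log(1 - 4 * p / 3)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise dissimilarities with zero diagonal."""

    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal not zero")
        if np.any(self.d < 0):
            raise ValueError("negative dissimilarity")


def distance_matrix(
    seqs: dict[str, str] | Sequence[tuple[str, str]], metric: str = "p"
) -> DistanceMatrix:
    """Pairwise distance matrix over aligned sequences ('p' or 'jc' metric)."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    labels = [i for i, _ in items]
    fn = {"p": p_distance, "jc": jc_distance}[metric]
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(items[i][1], items[j][1])
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor-joining (Saitou-Nei) on a distance matrix.

    Ties on the Q criterion break toward the smallest (i, j) index pair in
    the current label order, making the output deterministic even on
    degenerate (e.g. star-like) inputs.  Negative branch-length estimates
    are clamped to zero with a warning.  Returns an unrooted tree
    represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - (d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        new_d = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                new_d[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            du = (d[i, ka] + d[j, ka] - d[i, j]) / 2
            new_d[a, m - 2] = new_d[m - 2, a] = du
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    # terminal three-way join: star with closed-form branch lengths
    la = clamp((d[0, 1] + d[0, 2] - d[1, 2]) / 2)
    lb = clamp((d[0, 1] + d[1, 2] - d[0, 2]) / 2)
    lc = clamp((d[0, 2] + d[1, 2] - d[0, 1]) / 2)
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
    root = TreeNode(children=list(nodes))
    return root


def pair_tree(dm: DistanceMatrix) -> TreeNode:
    """Trivial two-taxon tree: a single edge split evenly at the root."""
    if len(dm.labels) != 2:
        raise ValueError("pair_tree needs exactly 2 taxa")
    a = TreeNode(name=dm.labels[0], length=dm.d[0, 1] / 2)
    b = TreeNode(name=dm.labels[1], length=dm.d[0, 1] / 2)
    return TreeNode(children=[a, b])
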