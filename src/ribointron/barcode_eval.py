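"""Terminal-taxon delineation and marker-region discriminability.

A *terminal taxon* is a group of identical or near-identical sequences
treated as one species-level unit.  Given core sequences, taxa are
delineated by single-linkage clustering under a small Hamming-difference
tolerance.  Marker regions (e.g. the 18S V4 and V9) are then evaluated:
taxa whose region haplotypes coincide *collapse* — they cannot be told
apart by that marker — and region-level NJ trees can be compared with
full-gene trees by clade recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from skbio import TreeNode

from .intron_grammar import DistanceMatrix, distance_matrix, nj_tree

__all__ = [
    "TerminalTaxon",
    "CollapseReport",
    "delineate_terminal_taxa",
    "collapse_report",
    "region_tree",
    "clade_recovery",
]


@dataclass
class TerminalTaxon:
    """One species-level unit: a set of (near-)identical sequences."""

    label: str
    members: list[str]
    representative: str


@dataclass
class CollapseReport:
    """Which terminal taxa a marker region fails to discriminate."""

    marker: str
    groups: list[list[str]]          # indistinguishable taxa, |group| >= 2
    discriminable_count: int         # taxa with a unique region haplotype
    incomplete: list[str] = field(default_factory=list)

    @property
    def n_collapsed_groups(self) -> int:
        return len(self.groups)


def _hamming(a: str, b: str) -> int:
    return sum(
        1 for x, y in zip(a, b) if x != y and x not in "N-" and y not in "N-"
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def delineate_terminal_taxa(
    cores: Mapping[str, str] | Sequence[tuple[str, str]],
    max_diff: int = 2,
) -> list[TerminalTaxon]:
    """Cluster core sequences into terminal taxa.

    Sequences are end-trimmed to the shortest length, then single-linkage
    clustered: two sequences link when their Hamming difference over the
    shared length (skipping N) is at most ``max_diff``.  Labels
    ``taxon_001``... are assigned in order of the lexicographically
    smallest member id of each cluster.
    """
    items = list(cores.items()) if isinstance(cores, Mapping) else list(cores)
    if not items:
        raise ValueError("no sequences to delineate")
    ids = [i for i, _ in items]
    shared = min(len(s) for _, s in items)
    trimmed = [s[:shared] for _, s in items]
    uf = _UnionFind(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if _hamming(trimmed[i], trimmed[j]) <= max_diff:
                uf.union(i, j)
    clusters: dict[int, list[str]] = {}
    for k, sid in enumerate(ids):
        clusters.setdefault(uf.find(k), []).append(sid)
    ordered = sorted(clusters.values(), key=lambda m: min(m))
    return [
        TerminalTaxon(label=f"taxon_{i:03d}", members=sorted(m), representative=min(m))
        for i, m in enumerate(ordered, start=1)
    ]


def collapse_report(
    regions: Mapping[str, Iterable[str]],
    marker: str = "",
    incomplete_marker: str = "N",
) -> CollapseReport:
    """Report which taxa a marker region cannot distinguish.

    ``regions`` maps each terminal taxon to its set of full-length region
    haplotypes.  Taxa sharing any identical haplotype fall in one collapsed
    group; taxa whose haplotypes are all unique count as discriminable.
    Haplotypes containing the incomplete marker (default 'N') or taxa with
    no haplotype at all are listed separately and excluded from equality
    testing.
    """
    complete: dict[str, set[str]] = {}
    incomplete: list[str] = []
    for taxon, haps in regions.items():
        usable = {h for h in haps if h and incomplete_marker not in h}
        if usable:
            complete[taxon] = usable
        else:
            incomplete.append(taxon)

    taxa = sorted(complete)
    uf = _UnionFind(len(taxa))
    index = {t: i for i, t in enumerate(taxa)}
    hap_owner: dict[str, str] = {}
    for t in taxa:
        for h in complete[t]:
            if h in hap_owner:
                uf.union(index[t], index[hap_owner[h]])
            else:
                hap_owner[h] = t
    clusters: dict[int, list[str]] = {}
    for t in taxa:
        clusters.setdefault(uf.find(index[t]), []).append(t)
    groups = sorted(
        (sorted(m) for m in clusters.values() if len(m) >= 2), key=lambda g: g[0]
    )
    discriminable = len(taxa) - sum(len(g) for g in groups)
    return CollapseReport(
        marker=marker,
        groups=[list(g) for g in groups],
        discriminable_count=discriminable,
        incomplete=sorted(incomplete),
    )


def region_tree(
    regions: Mapping[str, str],
    metric: str = "p",
) -> TreeNode:
    """NJ tree over a marker region, one haplotype per taxon.

    Duplicate haplotypes are dereplicated before tree building and
    re-attached as zero-length sibling leaves, so every input taxon
    appears as a leaf.
    """
    items = sorted(regions.items())
    by_hap: dict[str, list[str]] = {}
    for label, hap in items:
        by_hap.setdefault(hap, []).append(label)
    reps = {labels[0]: hap for hap, labels in by_hap.items()}
    if len(reps) < 3:
        raise ValueError(
            f"need at least 3 distinct haplotypes, got {len(reps)}"
        )
    dm = distance_matrix(reps, metric=metric)
    tree = nj_tree(dm)
    for hap, labels in by_hap.items():
        if len(labels) == 1:
            continue
        rep = labels[0]
        leaf = tree.find(rep)
        # leaf becomes an internal node carrying zero-length children
        leaf.name = None
        for lbl in labels:
            leaf.append(TreeNode(name=lbl, length=0.0))
    return tree


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Tip-sets induced by every edge of the (arbitrarily rooted) tree."""
    parts = set()
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        parts.add(tips)
    return parts


def is_monophyletic(tree: TreeNode, group: set[str]) -> bool:
    """Group monophyly on an unrooted tree via bipartition membership."""
    leaves = {t.name for t in tree.tips()}
    g = frozenset(group)
    if len(g) <= 1 or g == leaves:
        return True
    parts = _bipartitions(tree)
    return g in parts or frozenset(leaves - g) in parts


def clade_recovery(
    reference_tree: TreeNode,
    test_tree: TreeNode,
    groups: Mapping[str, Iterable[str]],
) -> tuple[float, dict[str, bool]]:
    """Fraction of groups monophyletic in both trees.

    Both trees must share the same leaf set; monophyly is evaluated as
    bipartition compatibility (a group is monophyletic iff some edge
    splits exactly that group).
    """
    ref_leaves = {t.name for t in reference_tree.tips()}
    test_leaves = {t.name for t in test_tree.tips()}
    if ref_leaves != test_leaves:
        diff = sorted(ref_leaves ^ test_leaves)
        raise ValueError(f"leaf sets differ: {diff}")
    per_group = {
        label: is_monophyletic(reference_tree, set(members))
        and is_monophyletic(test_tree, set(members))
        for label, members in groups.items()
    }
    if not per_group:
        raise ValueError("no groups to evaluate")
    return sum(per_group.values()) / len(per_group), per_group
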