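"""Truth-tabled generator of rDNA-like datasets.

Emulates the features of chaetocerotacean 18S/28S reference data that the
pipeline must handle: core sequences of realistic length (18S about
1669-1703 nt) evolved under Jukes-Cantor substitution on a known clade
tree, spliceosomal introns (96-199 nt, full splice-site grammar) and
group IC1-like introns (399-547 nt, conserved blocks alternating with
random spacers) implanted at fixed flank positions in a subset of clades,
truncated (partially sequenced) inserts, intra-individual
presence/absence polymorphism, and primer target sites embedded at known
coordinates.  Every implant is recorded in a machine-readable truth
table, so detection, classification, primer auditing and region
evaluation can all be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .intron_grammar import GrammarParams, match_iupac, scan_spliceosomal
from .primer_audit import reverse_complement
from .seqio import (
    MultipleAlignment,
    PrimerSpec,
    SequenceRecord,
    write_fasta,
    write_report,
)

__all__ = [
    "IntronSpec",
    "PrimerSite",
    "GeneratorConfig",
    "default_config",
    "simulate_core",
    "sample_spliceosomal_intron",
    "sample_group1_intron",
    "implant_introns",
    "generate_dataset",
]

BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = [
    "seq_id", "taxon", "gene", "p5", "p3", "family", "length",
    "complete", "present", "affected_primers", "affected_regions",
]


@dataclass(frozen=True)
class IntronSpec:
    """One intron location to implant: site, family, carriers, behaviour."""

    flank_pos: int                       # p5: insert goes between p5 and p5+1
    family: str                          # 'SP' or 'GI'
    carriers: tuple[str, ...]            # taxon ids carrying the intron
    length_range: tuple[int, int] | None = None
    presence_prob: float = 1.0
    truncation_prob: float = 0.0
    polymorphic_carriers: tuple[str, ...] = ()  # emit with/without copies


@dataclass(frozen=True)
class PrimerSite:
    """A primer whose exact target is embedded in the core at ``start`` (1-based)."""

    primer: PrimerSpec
    start: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.start + len(self.primer) - 1)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset (one gene)."""

    gene: str = "18S"
    n_clades: int = 7
    taxa_per_clade: int = 3
    core_length: int | None = None       # None: drawn from core_length_range
    core_length_range: tuple[int, int] = (1669, 1703)
    between_clade_div: float = 0.02      # expected substitutions/site
    within_clade_div: float = 0.0005
    intron_specs: list[IntronSpec] = field(default_factory=list)
    primer_sites: list[PrimerSite] = field(default_factory=list)
    regions: dict[str, tuple[str, str]] = field(default_factory=dict)
    intron_carrier_div: float = 0.02     # substitutions between carriers' introns
    include_reference: bool = True       # emit an intron-free 'REF' row
    tree_newick: str | None = None       # overrides the clade structure


def _concrete(iupac_seq: str, rng: np.random.Generator) -> str:
    """Deterministic-ish concrete expansion of an IUPAC string (modal base)."""
    from .intron_grammar import IUPAC_SETS

    return "".join(sorted(IUPAC_SETS[b])[0] for b in iupac_seq)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _clade_tree(config: GeneratorConfig) -> TreeNode:
    clades = []
    for c in range(1, config.n_clades + 1):
        leaves = [
            TreeNode(name=f"c{c}t{t}", length=config.within_clade_div)
            for t in range(1, config.taxa_per_clade + 1)
        ]
        clades.append(TreeNode(children=leaves, length=config.between_clade_div))
    return TreeNode(children=clades)


def simulate_core(
    config: GeneratorConfig, seed: int | np.random.Generator
) -> tuple[list[SequenceRecord], TreeNode, dict[str, str]]:
    """Evolve ungapped core sequences on the configured tree.

    The root sequence is uniform over ACGT; along each branch the number
    of substitutions is Poisson with mean (branch length x sequence
    length), each hitting a uniform position and switching to one of the
    three other bases.  Embedded primer targets are written into every
    sequence afterwards, so primer sites match their primers exactly
    unless the configuration says otherwise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.tree_newick is not None:
        tree = TreeNode.read([config.tree_newick])
    else:
        tree = _clade_tree(config)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length {node.length}")

    L = config.core_length
    if L is None:
        lo, hi = config.core_length_range
        L = int(rng.integers(lo, hi + 1))
    for spec in config.intron_specs:
        if not 1 <= spec.flank_pos <= L - 1:
            raise ValueError(
                f"intron flank position {spec.flank_pos} outside [1, {L - 1}]"
            )

    root_seq = rng.choice(BASES, size=L)

    def evolve(seq: np.ndarray, branch_len: float) -> np.ndarray:
        n_sub = rng.poisson(branch_len * L)
        if n_sub == 0:
            return seq
        seq = seq.copy()
        positions = rng.integers(0, L, size=n_sub)
        for pos in positions:
            current = seq[pos]
            options = [b for b in "ACGT" if b != current]
            seq[pos] = options[rng.integers(0, 3)]
        return seq

    leaf_seqs: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = evolve(seq, child.length or 0.0)
            if child.is_tip():
                leaf_seqs[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree, root_seq)

    # stamp exact primer targets into every sequence (and the root)
    def stamp(seq: np.ndarray) -> np.ndarray:
        seq = seq.copy()
        for site in config.primer_sites:
            target = _concrete(site.primer.sequence, rng)
            if site.primer.orientation == "reverse":
                target = reverse_complement(target)
            a, b = site.interval
            if b > L:
                raise ValueError(f"primer site {site.primer.name} exceeds core length")
            seq[a - 1 : b] = list(target)
        return seq

    clade_map: dict[str, str] = {}
    records = []
    for name in sorted(leaf_seqs):
        seq = stamp(leaf_seqs[name])
        clade_map[name] = name.split("t")[0] if name.startswith("c") else ""
        records.append(
            SequenceRecord(
                id=name, residues="".join(seq), taxon=name, gene=config.gene
            )
        )
    if config.include_reference:
        records.insert(
            0,
            SequenceRecord(
                id="REF",
                residues="".join(stamp(root_seq)),
                taxon="reference",
                gene=config.gene,
            ),
        )
    return records, tree, clade_map


def _weighted_motif(
    rng: np.random.Generator, consensus: str, modal: str, p_modal: float = 0.8
) -> str:
    """Sample a motif: the modal realisation 80% of the time, else a uniform
    draw from the consensus class."""
    from .intron_grammar import IUPAC_SETS

    if rng.random() < p_modal:
        return modal
    return "".join(
        sorted(IUPAC_SETS[b])[rng.integers(0, len(IUPAC_SETS[b]))] for b in consensus
    )


def sample_spliceosomal_intron(
    rng: np.random.Generator,
    len_range: tuple[int, int] = (96, 199),
    gene: str = "18S",
    params: GrammarParams = GrammarParams(),
) -> str:
    """Sample a spliceosomal intron that the grammar scanner accepts.

    Donor from GTDHNN (weighted toward GTAAGT), variable interior, branch
    from YTRAC (weighted toward TTAAC), a pyrimidine-rich tract, and an
    acceptor from YNHAG (weighted toward TACAG); in 28S mode the terminal
    hexamer is drawn from YTAMAG (weighted toward TTAAAG).  Total length
    uniform over ``len_range``.
    """
    lo, hi = len_range
    min_feasible = 6 + 5 + params.ct_window + 6 + 2  # donor+branch+tract+acceptor+slack
    if lo < max(min_feasible, params.min_len):
        raise ValueError(f"len_range minimum {lo} below grammar minimum span")
    for _ in range(100):
        total = int(rng.integers(lo, hi + 1))
        donor = _weighted_motif(rng, params.donor, "GTAAGT")
        branch = _weighted_motif(rng, params.branch, "TTAAC")
        if gene == "28S":
            acceptor = _weighted_motif(rng, params.acceptor_28s, "TTAAAG")
        else:
            acceptor = _weighted_motif(rng, params.acceptor, "TACAG")
        ct_len = int(rng.integers(params.ct_window, params.ct_window + 11))
        ct = "".join(
            rng.choice(list("CT")) if rng.random() < 0.85 else rng.choice(list("AG"))
            for _ in range(ct_len)
        )
        tail_len = int(rng.integers(0, 6))
        var_len = total - len(donor) - len(branch) - ct_len - tail_len - len(acceptor)
        if var_len < 0:
            continue
        intron = (
            donor
            + _random_dna(rng, var_len)
            + branch
            + ct
            + _random_dna(rng, tail_len)
            + acceptor
        )
        if scan_spliceosomal(intron, gene=gene, params=params) is not None:
            return intron
    raise RuntimeError("could not sample a grammar-conformant intron in 100 tries")


def sample_group1_intron(
    rng: np.random.Generator,
    len_range: tuple[int, int] = (399, 547),
    ancestral_core: str | None = None,
    n_blocks: int = 4,
    block_len: int = 45,
    block_mut: float = 0.03,
    params: GrammarParams = GrammarParams(),
) -> str:
    """Sample a group IC1-like intron: conserved blocks, random spacers.

    Blocks are low-mutation copies of an ancestral template (shared by
    introns sampled from the same template, so conserved-block extraction
    finds them); spacers are fresh random DNA.  The result is guaranteed
    not to open with a spliceosomal donor.
    """
    lo, hi = len_range
    total = int(rng.integers(lo, hi + 1))
    if ancestral_core is None:
        ancestral_core = _random_dna(rng, n_blocks * block_len)
    if len(ancestral_core) < n_blocks * block_len:
        raise ValueError("ancestral template shorter than the blocks it must seed")
    spacer_total = total - n_blocks * block_len
    if spacer_total < n_blocks + 1:
        raise ValueError(f"len_range too small for {n_blocks} blocks of {block_len}")
    cuts = np.sort(rng.integers(0, spacer_total + 1, size=n_blocks))
    spacer_lens = np.diff(np.concatenate([[0], cuts, [spacer_total]]))
    parts = [_random_dna(rng, int(spacer_lens[0]))]
    for k in range(n_blocks):
        block = list(ancestral_core[k * block_len : (k + 1) * block_len])
        for i in range(len(block)):
            if rng.random() < block_mut:
                block[i] = rng.choice([b for b in "ACGT" if b != block[i]])
        parts.append("".join(block))
        parts.append(_random_dna(rng, int(spacer_lens[k + 1])))
    intron = "".join(parts)
    if match_iupac(params.donor, intron[: len(params.donor)]):
        intron = "A" + intron[1:]  # forbid the spliceosomal donor
    return intron


def _mutate_checked(seq: str, rate: float, rng: np.random.Generator, checker) -> str:
    """Substitution-mutate a sequence, keeping the grammar property ``checker``."""
    for _ in range(10):
        chars = list(seq)
        n_sub = rng.poisson(rate * len(chars))
        for _ in range(n_sub):
            pos = int(rng.integers(0, len(chars)))
            chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
        mutated = "".join(chars)
        if checker(mutated):
            return mutated
    return seq


def implant_introns(
    cores: list[SequenceRecord],
    config: GeneratorConfig,
    seed: int | np.random.Generator,
    params: GrammarParams = GrammarParams(),
) -> tuple[MultipleAlignment, pd.DataFrame]:
    """Implant configured introns into core sequences; return alignment + truth.

    Carriers at one location share a common base intron differentiated by
    low-rate substitutions (mirroring intron sharing across related taxa).
    Polymorphic carriers are emitted as two copies, ``<id>a`` with and
    ``<id>b`` without their polymorphic introns.  Truncation replaces an
    intron by a 5'-anchored prefix whose last three bases are 'N'
    (unsequenced tail), flagged incomplete in the truth table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    specs = sorted(config.intron_specs, key=lambda s: s.flank_pos)
    for a, b in zip(specs, specs[1:]):
        if a.flank_pos == b.flank_pos:
            raise ValueError(f"two intron specs at flank position {a.flank_pos}")

    # copies: polymorphic carriers are duplicated
    poly_taxa = sorted({t for s in specs for t in s.polymorphic_carriers})
    copies: list[tuple[str, SequenceRecord]] = []
    for rec in cores:
        if rec.id in poly_taxa:
            copies.append((f"{rec.id}a", rec))
            copies.append((f"{rec.id}b", rec))
        else:
            copies.append((rec.id, rec))

    # per-location base introns
    base_introns: dict[int, str] = {}
    for s in specs:
        if s.family == "SP":
            rng_range = s.length_range or (96, 199)
            base_introns[s.flank_pos] = sample_spliceosomal_intron(
                rng, rng_range, gene=config.gene, params=params
            )
        elif s.family == "GI":
            rng_range = s.length_range or (399, 547)
            base_introns[s.flank_pos] = sample_group1_intron(
                rng, rng_range, params=params
            )
        else:
            raise ValueError(f"unknown intron family {s.family!r}")

    def sp_ok(seq: str) -> bool:
        return scan_spliceosomal(seq, gene=config.gene, params=params) is not None

    def gi_ok(seq: str) -> bool:
        return not match_iupac(params.donor, seq[: len(params.donor)])

    # decide every (copy, spec) implant
    implants: dict[tuple[str, int], tuple[str, bool]] = {}  # -> (sequence, complete)
    truth_rows = []
    for s in specs:
        checker = sp_ok if s.family == "SP" else gi_ok
        for taxon in s.carriers:
            taxon_copies = [cid for cid, rec in copies if rec.id == taxon]
            if not taxon_copies:
                raise ValueError(f"intron carrier {taxon!r} not among core sequences")
            present_draw = rng.random() <= s.presence_prob
            for cid in taxon_copies:
                present = present_draw
                if taxon in s.polymorphic_carriers:
                    present = cid.endswith("a")
                if not present:
                    truth_rows.append(
                        dict(
                            seq_id=cid, taxon=taxon, gene=config.gene,
                            p5=s.flank_pos, p3=s.flank_pos + 1, family=s.family,
                            length=0, complete=True, present=False,
                        )
                    )
                    continue
                intron = _mutate_checked(
                    base_introns[s.flank_pos], config.intron_carrier_div, rng, checker
                )
                complete = True
                if rng.random() < s.truncation_prob:
                    cut = int(rng.integers(
                        max(10, int(0.3 * len(intron))), int(0.8 * len(intron)) + 1
                    ))
                    intron = intron[: cut - 3] + "NNN"
                    complete = False
                implants[(cid, s.flank_pos)] = (intron, complete)
                truth_rows.append(
                    dict(
                        seq_id=cid, taxon=taxon, gene=config.gene,
                        p5=s.flank_pos, p3=s.flank_pos + 1, family=s.family,
                        length=len(intron), complete=complete, present=True,
                    )
                )

    # assemble the alignment gene-position block by block
    widths = {
        s.flank_pos: max(
            [len(implants[(cid, s.flank_pos)][0])
             for cid, _ in copies if (cid, s.flank_pos) in implants],
            default=0,
        )
        for s in specs
    }
    active_specs = [s for s in specs if widths[s.flank_pos] > 0]
    aligned_records = []
    for cid, rec in copies:
        pieces = []
        prev = 0
        for s in active_specs:
            pieces.append(rec.residues[prev : s.flank_pos])
            w = widths[s.flank_pos]
            if (cid, s.flank_pos) in implants:
                intron, _ = implants[(cid, s.flank_pos)]
                pieces.append(intron + "-" * (w - len(intron)))
            else:
                pieces.append("-" * w)
            prev = s.flank_pos
        pieces.append(rec.residues[prev:])
        aligned_records.append(
            replace(rec, id=cid, residues="".join(pieces), aligned=True)
        )
    aln = MultipleAlignment(aligned_records)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS[:-2])
    truth["affected_primers"] = [
        ",".join(
            site.primer.name
            for site in config.primer_sites
            if site.interval[0] <= row.p5 <= site.interval[1] - 1
        )
        for row in truth.itertuples()
    ]
    primer_by_name = {site.primer.name: site for site in config.primer_sites}
    region_spans = {}
    for name, (f, r) in config.regions.items():
        region_spans[name] = (
            primer_by_name[f].interval[0], primer_by_name[r].interval[1]
        )
    truth["affected_regions"] = [
        ",".join(
            name for name, (a, b) in region_spans.items() if a <= row.p5 <= b - 1
        )
        for row in truth.itertuples()
    ]
    return aln, truth


def default_config(gene: str = "18S", scenario: str = "default") -> GeneratorConfig:
    """The default study conditions.

    18S: 19 intron locations (two group-I, at the 4th and 12th) carried
    only by taxa in clades 1 and 7 of 7, with embedded V4- and V9-style
    primer pairs bracketing regions of roughly 400 and 145 core columns;
    one location polymorphic within a strain and the 3'-most location
    frequently truncated.  28S: one spliceosomal location.  The stress
    scenarios shorten one marker's usable region by concentrating introns
    there, for marker-contrast experiments.
    """
    if gene == "28S":
        primers: list[PrimerSite] = []
        specs = [
            IntronSpec(700, "SP", ("c1t1", "c7t1", "c7t2")),
        ]
        return GeneratorConfig(
            gene="28S",
            core_length=760,
            core_length_range=(680, 765),
            intron_specs=specs,
            primer_sites=primers,
        )

    v4f = PrimerSpec("V4f-demo", "forward", "CCAGCASCYGCGGTAATTCC", 3)
    v4r = PrimerSpec("V4r-demo", "reverse", "ACTTTCGTTCTTGATYRA", 3)
    v9f = PrimerSpec("V9f-demo", "forward", "TTGTACACACCGCCC", 3)
    v9r = PrimerSpec("V9r-demo", "reverse", "CCTTCYGCAGGTTCACCTAC", 3)
    primer_sites = [
        PrimerSite(v4f, 460),    # interval [460, 479]
        PrimerSite(v4r, 880),    # interval [880, 897]
        PrimerSite(v9f, 1470),   # interval [1470, 1484]
        PrimerSite(v9r, 1630),   # interval [1630, 1649]
    ]
    clade17 = ["c1t1", "c1t2", "c1t3", "c7t1", "c7t2", "c7t3"]
    sp = lambda pos, *taxa, **kw: IntronSpec(pos, "SP", tuple(taxa), **kw)
    specs = [
        sp(385, "c7t1", "c7t2"),
        sp(442, "c1t1", "c7t1", "c7t3"),
        sp(548, "c7t2"),
        IntronSpec(549, "GI", ("c1t1", "c1t2", "c7t1", "c7t3")),
        sp(888, "c7t1", "c7t2"),            # inside V4r site
        sp(889, "c7t3"),                    # inside V4r site
        sp(891, "c1t2", "c1t3"),            # inside V4r site
        sp(981, "c7t2", "c7t3"),
        sp(989, "c1t1", "c7t1"),
        sp(1011, "c7t1", polymorphic_carriers=("c7t1",)),
        sp(1147, "c1t3", "c7t2"),
        IntronSpec(1151, "GI", ("c7t2", "c7t3")),
        sp(1195, "c1t1", "c7t1", "c7t2"),
        sp(1257, "c7t3"),
        sp(1274, "c1t2"),
        sp(1414, "c7t1", "c7t2"),
        sp(1478, "c1t1", "c7t3"),           # inside V9f site
        sp(1560, "c7t1"),
        sp(1640, "c1t1", "c7t2", truncation_prob=1.0),  # inside V9r site
    ]
    if scenario == "v9_stress":
        specs += [sp(1500, *clade17[:2]), sp(1530, *clade17[3:5])]
    elif scenario == "v4_stress":
        specs += [sp(600, *clade17[:2]), sp(700, *clade17[3:5])]
    elif scenario != "default":
        raise ValueError(f"unknown scenario {scenario!r}")
    return GeneratorConfig(
        gene="18S",
        intron_specs=specs,
        primer_sites=primer_sites,
        regions={"V4": ("V4f-demo", "V4r-demo"), "V9": ("V9f-demo", "V9r-demo")},
    )


def generate_dataset(
    config: GeneratorConfig, seed: int, outdir
) -> dict:
    """Generate one dataset and write its files; deterministic per seed.

    Writes ``cores.fasta`` (unaligned per-copy sequences with introns),
    ``aligned.fasta``, ``core_aligned.fasta`` (pre-implant cores),
    ``truth.tsv``, ``primers.tsv`` and ``tree.nwk`` under ``outdir`` and
    returns the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cores, tree, clade_map = simulate_core(config, rng)
    aln, truth = implant_introns(cores, config, rng)

    unaligned = [
        replace(rec, residues=rec.ungapped(), aligned=False) for rec in aln.records
    ]
    write_fasta(unaligned, outdir / "cores.fasta")
    write_fasta(aln, outdir / "aligned.fasta")
    write_fasta(cores, outdir / "core_aligned.fasta")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_report(
        [
            dict(
                name=s.primer.name,
                orientation=s.primer.orientation,
                sequence=s.primer.sequence,
                critical_window=s.primer.critical_window,
            )
            for s in config.primer_sites
        ],
        outdir / "primers.tsv",
        columns=["name", "orientation", "sequence", "critical_window"],
    )
    tree.write(str(outdir / "tree.nwk"))
    return {
        "cores": cores,
        "alignment": aln,
        "truth": truth,
        "tree": tree,
        "clade_map": clade_map,
        "config": config,
    }
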