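"""Synthetic-data generator for the whole pipeline.

Emits every input the analysis consumes — a time-calibrated species tree
with a designated foreground branch and high-latitude / sub-Antarctic tip
classes, per-locus alignments with a planted rate shift on the foreground
branch, gene/CNE annotations wired so the planted ontology term tags the
genes whose regulatory domains catch the shifted CNEs, per-exon pileup
summaries with planted truncating variants, and labelled cell-mask images
of circular versus elliptical cells — together with a ground-truth record
of everything that was planted.

All randomness derives from ``SimulationConfig.seed``; identical configs
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import domains as dom
from .phylo import STATES, SubstitutionModel, TreeModel

STOP_CODONS = {"TAA", "TAG", "TGA"}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class VariantSpec:
    """One planted variant in the pileup data."""

    species: str
    gene_id: str
    kind: str  # frameshift | nonsense | missense | inframe_indel | whole_gene_deletion
    position: int | None = None  # gene-relative 0-based; None -> auto
    fixed: bool = True
    allele_fraction: float = 1.0
    indel_length: int = 4
    depth: int | None = None  # overrides the config-wide pileup depth


@dataclass
class MaskClassSpec:
    """One morphological class of synthetic cells."""

    name: str
    n_cells: int = 100
    aspect_ratio: float = 1.0
    radius_px: float = 30.0
    pixel_size_um: float = 0.2


def _default_variants() -> list[VariantSpec]:
    return [
        VariantSpec("sp01", "p000", "frameshift", position=10, indel_length=4),
        VariantSpec("sp01", "p001", "nonsense"),
        # below the 3-read support floor: must never be called
        VariantSpec("sp02", "p000", "frameshift", position=50, indel_length=2, depth=2),
        VariantSpec("sp02", "p002", "whole_gene_deletion"),
        VariantSpec("sp03", "p003", "inframe_indel", position=21, indel_length=3),
        VariantSpec("sp03", "p001", "missense", fixed=False, allele_fraction=0.4),
    ]


def _default_masks() -> list[MaskClassSpec]:
    return [
        MaskClassSpec("round", n_cells=100, aspect_ratio=1.0),
        MaskClassSpec("elliptical", n_cells=100, aspect_ratio=2.0),
    ]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the desk-scale study design: a 20-species clade whose
    crown age falls in the 18.6-23.9 Ma calibration window, 300 conserved
    elements of 300 bp of which 50 evolve at four times the neutral rate
    on the foreground (trait-loss ancestor) branch, 100 genes and a
    20-term ontology with a single planted term.
    """

    seed: int = 0
    n_species: int = 20
    root_age_interval: tuple[float, float] = (18.6, 23.9)
    foreground_branch: str | None = None  # None -> auto-selected clade
    ha_tips: tuple[str, ...] | None = None
    sa_tips: tuple[str, ...] | None = None
    n_loci: int = 300
    locus_length: int = 300
    fraction_shifted: float = 50 / 300
    shift_scale: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    kappa: float = 2.5
    clock_rate: float = 0.012  # substitutions / site / Ma
    dropout_rate: float = 0.0  # per-locus per-species missingness
    genome_length: int = 20_000_000
    n_genes: int = 100
    n_cnes: int | None = None  # None -> n_loci (one CNE per locus)
    n_terms: int = 20
    # seed genes hosting the shifted CNEs; a few percent of all genes,
    # matching the gene-count fraction of a disease-ontology term
    planted_term_size: int = 4
    pileup_depth: int = 20
    pileup_species: tuple[str, ...] = ("sp01", "sp02", "sp03", "sp04")
    pileup_genes: int = 5
    variant_spec: list[VariantSpec] = field(default_factory=_default_variants)
    mask_spec: list[MaskClassSpec] = field(default_factory=_default_masks)
    grayscale_masks: bool = False

    def __post_init__(self):
        if not (0.0 <= self.fraction_shifted <= 1.0):
            raise SimulationError("fraction_shifted must be in [0, 1]")
        if self.shift_scale <= 0:
            raise SimulationError("shift_scale must be positive")
        if self.n_species < 2:
            raise SimulationError("need at least 2 species")
        lo, hi = self.root_age_interval
        if not lo < hi:
            raise SimulationError("root_age_interval must satisfy min < max")
        if self.n_cnes is None:
            self.n_cnes = self.n_loci

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per simulator component."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    shifted_locus_ids: set = field(default_factory=set)
    planted_term_id: str | None = None
    planted_term_genes: set = field(default_factory=set)
    true_branch_scales: dict = field(default_factory=dict)
    planted_variants: list = field(default_factory=list)
    cell_class_labels: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, (set, frozenset)):
                return sorted(x)
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            raise TypeError(type(x))

        return json.dumps(dataclasses.asdict(self), default=conv, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def simulate_tree(config: SimulationConfig) -> TreeModel:
    """Yule topology rescaled to a crown age drawn from the calibration
    interval, with foreground branch and HA/SA tip classes attached.

    The returned :class:`TreeModel` carries branch lengths in expected
    substitutions per site (time x ``clock_rate``); the time tree itself
    is available as ``.time_newick`` (lengths in Ma) and the drawn crown
    age as ``.root_age``.
    """
    rng = config.rng(1)
    pyrng = random.Random(int(rng.integers(2**31)))
    if config.n_species == 2:
        # only one topology exists; build the cherry directly
        tree = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
    else:
        from dendropy.model import birthdeath

        tree = birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=config.n_species,
            rng=pyrng,
        )
    tree.is_rooted = True
    tree.seed_node.edge.length = None  # no stem edge on the crown tree
    if config.n_species > 2:
        # the generator stops exactly at the n-th split, leaving the last
        # cherry with zero-length tips; sample the tree a further
        # Exp(n * birth_rate) later (the waiting time to the next split)
        # so all terminal branches are positive
        extra = float(rng.exponential(1.0 / config.n_species))
        for leaf in tree.leaf_node_iter():
            leaf.edge.length += extra
    # deterministic tip labels sp01..spNN in postorder
    leaves = [nd for nd in tree.postorder_node_iter() if nd.is_leaf()]
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon.label = f"sp{i:02d}"
    # internal labels i0.. in postorder (skip root: no branch)
    k = 0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        nd.label = f"i{k}"
        k += 1
    # rescale to the drawn crown age
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    age = float(rng.uniform(*config.root_age_interval))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth * age

    # foreground branch: configured, or the internal branch whose clade is
    # closest to a quarter of the species (the trait-loss ancestor)
    internal = [
        nd
        for nd in tree.postorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
    ]
    # children of the root are excluded from auto-selection: under a
    # reversible model only the sum of the two root edges is identifiable,
    # so a rate shift planted there cannot be attributed to one branch
    deep = [nd for nd in internal if nd.parent_node.parent_node is not None]
    if config.foreground_branch is not None:
        fg = config.foreground_branch
        known = {nd.label for nd in internal} | {l.taxon.label for l in leaves}
        if fg not in known:
            raise SimulationError(f"foreground branch {fg!r} not in tree")
    elif deep:
        target = max(2, round(config.n_species / 4))
        best = min(
            deep,
            key=lambda nd: (abs(len(nd.leaf_nodes()) - target), nd.label),
        )
        fg = best.label
    elif internal:
        fg = internal[0].label
    else:  # two-species cherry: no internal branch exists
        fg = leaves[0].taxon.label

    model = SubstitutionModel.hky(config.base_freqs, config.kappa)
    time_newick = (
        tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    )
    # substitution-scale copy for sequence evolution and inference
    sub_tree = dendropy.Tree(tree)
    for edge in sub_tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * config.clock_rate

    tm = TreeModel(sub_tree, model, foreground_branch=fg)
    fg_clade = tm.clade_tips(fg)
    if config.ha_tips is not None:
        ha = set(config.ha_tips)
        sa = (
            set(config.sa_tips)
            if config.sa_tips is not None
            else set(tm.tip_labels()) - ha
        )
    else:
        ha, sa = set(fg_clade), set(tm.tip_labels()) - set(fg_clade)
    all_tips = set(tm.tip_labels())
    if not (ha | sa) <= all_tips:
        raise SimulationError("ha_tips/sa_tips contain unknown tip labels")
    tm.tip_classes = {t: ("HA" if t in ha else "SA" if t in sa else "other") for t in all_tips}
    tm.time_newick = time_newick
    tm.root_age = age
    tm.clock_rate = config.clock_rate
    return tm


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------


def _evolve_alignment(
    tree: TreeModel,
    n_sites: int,
    rng: np.random.Generator,
    branch_scales: dict[str, float] | None = None,
) -> dict[str, str]:
    idx = tree.index()
    model = tree.model
    scales = branch_scales or {}
    states = {idx.root: rng.choice(4, size=n_sites, p=model.freqs)}
    for v in reversed(idx.postorder):  # preorder
        if v == idx.root:
            continue
        t = idx.blen[v] * scales.get(idx.branch_id[v], 1.0)
        p = model.transition_matrix(t)
        parent = states[idx.parent[v]]
        out = np.empty(n_sites, dtype=np.int64)
        for s in range(4):
            m = parent == s
            if m.any():
                out[m] = rng.choice(4, size=int(m.sum()), p=p[s])
        states[v] = out
    return {
        idx.tip_label[v]: "".join(STATES[i] for i in states[v])
        for v in idx.postorder
        if idx.is_tip[v]
    }


def locus_ids(config: SimulationConfig) -> list[str]:
    return [f"cne{i:04d}" for i in range(config.n_loci)]


def simulate_loci(
    tree: TreeModel, config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[dict[str, dict[str, str]], GroundTruth]:
    """Evolve one alignment per locus; shifted loci get the foreground
    branch length multiplied by ``shift_scale``."""
    if config.locus_length < 1:
        raise SimulationError("locus_length must be >= 1")
    rng = config.rng(2)
    truth = truth or GroundTruth()
    ids = locus_ids(config)
    n_shift = round(config.fraction_shifted * config.n_loci)
    shifted = set(rng.choice(ids, size=n_shift, replace=False)) if n_shift else set()
    truth.shifted_locus_ids = shifted
    fg = tree.foreground_branch
    truth.true_branch_scales = {fg: config.shift_scale} if shifted else {}
    scales = {fg: config.shift_scale} if fg else {}
    out = {}
    tips = tree.tip_labels()
    for lid in ids:
        aln = _evolve_alignment(
            tree, config.locus_length, rng, scales if lid in shifted else None
        )
        if config.dropout_rate > 0:
            keep = rng.random(len(tips)) >= config.dropout_rate
            aln = {t: s for (t, s), k in zip(aln.items(), keep) if k}
            if not aln:  # keep at least one species
                aln = {tips[0]: "N" * config.locus_length}
        out[lid] = aln
    return out, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def _place_nonoverlapping(rng, occupied, lo, hi, length, retries=500):
    """Draw a start in [lo, hi-length) whose interval is free."""
    if hi - lo < length:
        raise SimulationError("placement window smaller than feature")
    for _ in range(retries):
        start = int(rng.integers(lo, hi - length))
        if not occupied.overlaps(start, start + length):
            occupied.addi(start, start + length)
            return start
    raise SimulationError("could not place feature without overlap")


def simulate_annotation_set(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene models, CNE intervals and a small ontology with one planted term.

    Shifted CNEs are placed inside the regulatory domains of a seed set of
    planted genes; the planted term is then defined as *exactly* the genes
    whose extended domains contain a shifted CNE (seed genes plus any
    neighbour whose domain happens to catch one). Decoy terms are random
    gene sets.
    """
    from intervaltree import IntervalTree

    rng = config.rng(3)
    if config.n_genes < 1 or config.n_cnes < 1:
        raise SimulationError("need at least one gene and one CNE")
    need = config.n_genes * 20_000 + config.n_cnes * config.locus_length * 2
    if config.genome_length < need:
        raise SimulationError(
            f"genome_length {config.genome_length} too small for "
            f"{config.n_genes} genes and {config.n_cnes} CNEs"
        )
    chrom = "chr1"
    # gene TSSs: uniform draw, resampled until min spacing holds
    spacing = 10_000
    while True:
        tss = np.sort(rng.integers(spacing, config.genome_length - spacing, config.n_genes))
        if config.n_genes == 1 or np.diff(tss).min() >= spacing:
            break
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:03d}" for i in range(config.n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": strands,
        }
    )
    chrom_sizes = {chrom: config.genome_length}
    domain_list = dom.compute_domains(genes, chrom_sizes)
    dom_by_gene = {d.gene_id: d for d in domain_list}

    ids = locus_ids(config)[: config.n_cnes]
    shifted = [i for i in ids if i in truth.shifted_locus_ids]
    unshifted = [i for i in ids if i not in truth.shifted_locus_ids]
    L = config.locus_length
    occupied = IntervalTree()
    starts: dict[str, int] = {}
    # seed genes hosting the shifted CNEs
    n_seed = min(config.planted_term_size, config.n_genes)
    seed_genes = list(rng.choice(genes.gene_id.to_numpy(), size=n_seed, replace=False))
    for j, cid in enumerate(shifted):
        d = dom_by_gene[seed_genes[j % n_seed]]
        starts[cid] = _place_nonoverlapping(rng, occupied, d.ext_start, d.ext_end, L)
    for cid in unshifted:
        starts[cid] = _place_nonoverlapping(rng, occupied, 0, config.genome_length, L)
    cnes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [starts[c] for c in ids],
            "end": [starts[c] + L for c in ids],
            "name": ids,
        }
    ).sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)

    assignment = dom.assign_cnes(cnes, domain_list)
    planted_genes = sorted(
        {g for cid in shifted for g in assignment[cid]}
    )
    planted_term = "T000"
    term_rows = [(planted_term, g) for g in planted_genes]
    names = {planted_term: "planted erythroid-like set", "T_ROOT": "root"}
    # decoys are true nulls: drawn from genes whose domains caught no
    # shifted CNE, so no planted signal leaks into them
    decoy_pool = np.array(sorted(set(genes.gene_id) - set(planted_genes)))
    decoy_size = max(5, n_seed)
    for k in range(1, config.n_terms):
        tid = f"T{k:03d}"
        names[tid] = f"decoy set {k}"
        for g in rng.choice(decoy_pool, size=min(decoy_size, len(decoy_pool)), replace=False):
            term_rows.append((tid, g))
    term_genes = pd.DataFrame(term_rows, columns=["term_id", "gene_id"])
    parents = pd.DataFrame(
        {
            "term_id": [f"T{k:03d}" for k in range(config.n_terms)],
            "parent_id": "T_ROOT",
        }
    )
    truth.planted_term_id = planted_term
    truth.planted_term_genes = set(planted_genes)
    return genes, cnes, term_genes, parents


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


_CODONS = [
    a + b + c
    for a in STATES
    for b in STATES
    for c in STATES
    if a + b + c not in STOP_CODONS
]


def _random_cds(rng, n_codons: int) -> str:
    body = "".join(rng.choice(_CODONS, size=n_codons - 1))
    return body + "TAA"


def _nonsense_site(cds: str, rng) -> tuple[int, str, str]:
    """A substitution position creating a premature stop."""
    n_codons = len(cds) // 3
    order = rng.permutation(n_codons - 1)  # exclude the terminal codon
    for ci in order:
        codon = cds[3 * ci : 3 * ci + 3]
        for off in range(3):
            for alt in STATES:
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1 :]
                if mutated in STOP_CODONS:
                    return 3 * ci + off, codon[off], alt
    raise SimulationError("no nonsense-creating site found")


def _missense_site(cds: str, rng) -> tuple[int, str, str]:
    from Bio.Seq import Seq

    n_codons = len(cds) // 3
    order = rng.permutation(n_codons - 1)
    for ci in order:
        codon = cds[3 * ci : 3 * ci + 3]
        for off in range(3):
            for alt in STATES:
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1 :]
                if mutated in STOP_CODONS:
                    continue
                if str(Seq(mutated).translate()) != str(Seq(codon).translate()):
                    return 3 * ci + off, codon[off], alt
    raise SimulationError("no missense site found")


def simulate_pileups(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-exon read-support table with planted variants.

    Returns ``(pileups, exon_table, truth)``. The exon table holds the
    reference coding exons (gene_id, exon_index, sequence); pileup rows
    are (species, gene, exon, pos, ref, alt, support, depth) with one
    baseline coverage row per exon (ref = alt = '.') plus one row per
    planted variant. Fixed variants are supported by every covering read;
    a whole-gene deletion zeroes the coverage of all exons of that gene
    for that species.
    """
    if config.pileup_depth < 1:
        raise SimulationError("pileup_depth must be >= 1")
    rng = config.rng(4)
    truth = truth or GroundTruth()
    n_exons = 3
    exon_rows = []
    cds: dict[str, str] = {}
    exon_bounds: dict[str, list[tuple[int, int]]] = {}
    for gi in range(config.pileup_genes):
        gid = f"p{gi:03d}"
        seq = _random_cds(rng, n_codons=60)  # 180 bp
        cds[gid] = seq
        step = len(seq) // n_exons
        bounds = [
            (k * step, (k + 1) * step if k < n_exons - 1 else len(seq))
            for k in range(n_exons)
        ]
        exon_bounds[gid] = bounds
        for k, (lo, hi) in enumerate(bounds):
            exon_rows.append((gid, k, seq[lo:hi]))
    exon_table = pd.DataFrame(exon_rows, columns=["gene_id", "exon_index", "sequence"])

    deleted = {
        (v.species, v.gene_id)
        for v in config.variant_spec
        if v.kind == "whole_gene_deletion"
    }
    rows = []
    for sp in config.pileup_species:
        for gid in cds:
            depth = 0 if (sp, gid) in deleted else config.pileup_depth
            for k, (lo, hi) in enumerate(exon_bounds[gid]):
                rows.append((sp, gid, k, lo, ".", ".", 0, depth))

    planted = []
    for v in config.variant_spec:
        if v.gene_id not in cds:
            raise SimulationError(f"unknown pileup gene {v.gene_id!r}")
        seq = cds[v.gene_id]
        depth = v.depth if v.depth is not None else config.pileup_depth
        if v.kind == "whole_gene_deletion":
            planted.append(
                {"species": v.species, "gene_id": v.gene_id, "kind": v.kind,
                 "position": None, "ref": None, "alt": None,
                 "support": 0, "depth": 0, "fixed": True}
            )
            continue
        if v.kind in ("frameshift", "inframe_indel"):
            pos = v.position if v.position is not None else int(rng.integers(3, len(seq) // 2))
            if not (0 <= pos < len(seq) - v.indel_length - 1):
                raise SimulationError(f"variant position {pos} outside gene {v.gene_id}")
            ref = seq[pos : pos + v.indel_length + 1]
            alt = seq[pos]
        elif v.kind == "nonsense":
            pos, refb, altb = _nonsense_site(seq, rng)
            ref, alt = refb, altb
        elif v.kind == "missense":
            pos, refb, altb = _missense_site(seq, rng)
            ref, alt = refb, altb
        else:
            raise SimulationError(f"unknown variant kind {v.kind!r}")
        if v.fixed:
            support = depth
        else:
            support = int(rng.binomial(depth, v.allele_fraction))
        exon_idx = next(
            k for k, (lo, hi) in enumerate(exon_bounds[v.gene_id]) if lo <= pos < hi
        )
        rows.append((v.species, v.gene_id, exon_idx, pos, ref, alt, support, depth))
        planted.append(
            {"species": v.species, "gene_id": v.gene_id, "kind": v.kind,
             "position": pos, "ref": ref, "alt": alt,
             "support": support, "depth": depth, "fixed": bool(v.fixed)}
        )
    pileups = pd.DataFrame(
        rows,
        columns=["species", "gene", "exon", "pos", "ref", "alt", "support", "depth"],
    )
    truth.planted_variants = planted
    return pileups, exon_table, truth


# ---------------------------------------------------------------------------
# cell masks
# ---------------------------------------------------------------------------


def simulate_masks(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[np.ndarray, np.ndarray, GroundTruth, float]:
    """Labelled image of non-touching filled ellipses.

    Returns ``(label_image, mask, truth, pixel_size_um)``: integer labels
    1..N (0 = background), the binary union mask, and the ground-truth
    particle->class map in ``truth.cell_class_labels``. Particles are laid
    out on a jittered grid so they can touch neither each other nor the
    image border. With ``config.grayscale_masks`` the binary mask can be
    turned into a noisy grayscale rendering via :func:`grayscale_render`.
    """
    from skimage.draw import ellipse as draw_ellipse

    rng = config.rng(5)
    truth = truth or GroundTruth()
    spec = config.mask_spec
    if not spec:
        raise SimulationError("mask_spec is empty")
    px = spec[0].pixel_size_um
    if any(abs(c.pixel_size_um - px) > 1e-12 for c in spec):
        raise SimulationError("all mask classes must share a pixel size")
    for c in spec:
        if c.aspect_ratio < 1.0:
            raise SimulationError("aspect_ratio must be >= 1")

    particles = [
        (c.name, c.radius_px * np.sqrt(c.aspect_ratio), c.radius_px / np.sqrt(c.aspect_ratio))
        for c in spec
        for _ in range(c.n_cells)
    ]
    if not particles:
        raise SimulationError("no cells requested")
    max_axis = max(a for _, a, _ in particles)
    cell = int(np.ceil(2 * max_axis)) + 8  # grid pitch; >=3 px clearance
    n = len(particles)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    H = nrow * cell + 8
    W = ncol * cell + 8
    labels = np.zeros((H, W), dtype=np.int32)
    order = rng.permutation(n)
    class_of: dict[int, str] = {}
    for slot, pidx in enumerate(order):
        pidx = int(pidx)
        name, a, b = particles[pidx]
        r, ccol = divmod(slot, ncol)
        cy = 4 + r * cell + cell // 2
        cx = 4 + ccol * cell + cell // 2
        jitter = (cell // 2) - int(np.ceil(a)) - 3
        if jitter < 0:
            raise SimulationError("cells too large for the placement grid")
        cy += int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        cx += int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        theta = float(rng.uniform(0, np.pi))
        rr, cc = draw_ellipse(cy, cx, b, a, shape=labels.shape, rotation=theta)
        labels[rr, cc] = pidx + 1
        class_of[pidx + 1] = name
    truth.cell_class_labels = class_of
    return labels, labels > 0, truth, px


def grayscale_render(
    mask: np.ndarray, rng: np.random.Generator, fg: int = 60, bg: int = 200, noise_sd: float = 8.0
) -> np.ndarray:
    """Noisy grayscale rendering (dark cells on a light background)."""
    img = np.where(mask, float(fg), float(bg))
    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# fixture directory writer (used by the CLI)
# ---------------------------------------------------------------------------


def write_fasta(aln: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(aln):
            fh.write(f">{name}\n{aln[name]}\n")


def simulate_all(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate every fixture into a directory, plus a ground-truth manifest."""
    out = Path(outdir)
    (out / "loci").mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()
    tree = simulate_tree(config)
    (out / "species_tree.nwk").write_text(tree.as_newick())
    (out / "species_tree_time.nwk").write_text(tree.time_newick)
    loci, truth = simulate_loci(tree, config, truth)
    for lid, aln in loci.items():
        write_fasta(aln, out / "loci" / f"{lid}.fa")
    genes, cnes, term_genes, parents = simulate_annotation_set(config, truth)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    cnes.to_csv(out / "cnes.bed", sep="\t", index=False, header=False,
                columns=["chrom", "start", "end", "name"])
    term_genes.to_csv(out / "ontology_genes.tsv", sep="\t", index=False)
    parents.to_csv(out / "ontology_parents.tsv", sep="\t", index=False)
    pileups, exon_table, truth = simulate_pileups(config, truth)
    pileups.to_csv(out / "pileups.tsv", sep="\t", index=False)
    exon_table.to_csv(out / "exons.tsv", sep="\t", index=False)
    label_img, mask, truth, px = simulate_masks(config, truth)
    import imageio.v3 as iio

    iio.imwrite(out / "cells_mask.png", (mask * 255).astype(np.uint8))
    if config.grayscale_masks:
        gray = grayscale_render(mask, config.rng(6))
        iio.imwrite(out / "cells_gray.png", gray)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "foreground_branch": tree.foreground_branch,
        "tip_classes": tree.tip_classes,
        "root_age_ma": tree.root_age,
        "pixel_size_um": px,
        "ground_truth": json.loads(truth.to_json()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return truth
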