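"""Truncating-variant screening, clinical-site mapping and pleiotropy.

Covers the coding-side analyses: assembling gene sequences from ordered
exon pieces, calling truncating variants (frameshift, premature stop,
whole-gene deletion) from per-exon read-support summaries with a
three-read floor, mapping species missense variants onto human
clinical-variant sites through a protein alignment, scoring pleiotropy
from a phenotype ontology, classifying erythroid-biased expression, and
the loss-of-function x pleiotropy association test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

STOP_CODONS = {"TAA", "TAG", "TGA"}
MIN_TRUNCATION_READS = 3


class ScreenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gene assembly
# ---------------------------------------------------------------------------


@dataclass
class GeneSequence:
    gene_id: str
    species: str | None
    exons: list[str | None]  # reference order; None = missing exon
    offsets: list[int]  # start offset of each present exon in `sequence`
    sequence: str  # concatenation of present exons
    missing_exons: list[int] = field(default_factory=list)


def assemble_gene_sequence(exon_table, species: str | None = None) -> GeneSequence:
    """Concatenate exons in reference order into one gene sequence.

    ``exon_table`` is a DataFrame with columns (gene_id, exon_index,
    sequence) or an iterable of such records for a single gene. An exon
    supplied more than once must be identical (isoform duplicates are
    collapsed); conflicting copies are an error. Missing indices leave a
    recorded gap.
    """
    if isinstance(exon_table, pd.DataFrame):
        recs = [
            (str(r.gene_id), int(r.exon_index), str(r.sequence))
            for r in exon_table.itertuples()
        ]
    else:
        recs = [(str(g), int(i), str(s)) for g, i, s in exon_table]
    if not recs:
        raise ScreenError("no exon records")
    gids = {g for g, _, _ in recs}
    if len(gids) != 1:
        raise ScreenError(f"exon records span several genes: {sorted(gids)}")
    (gene_id,) = gids
    by_idx: dict[int, str] = {}
    for _, i, s in recs:
        if i in by_idx and by_idx[i] != s:
            raise ScreenError(f"conflicting sequences for exon {i} of {gene_id}")
        by_idx[i] = s
    n = max(by_idx) + 1
    exons = [by_idx.get(i) for i in range(n)]
    missing = [i for i, e in enumerate(exons) if e is None]
    seq_parts, offsets, pos = [], [], 0
    for e in exons:
        offsets.append(pos)
        if e is not None:
            seq_parts.append(e)
            pos += len(e)
    return GeneSequence(
        gene_id=gene_id,
        species=species,
        exons=exons,
        offsets=offsets,
        sequence="".join(seq_parts),
        missing_exons=missing,
    )


# ---------------------------------------------------------------------------
# truncation calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    species: str
    gene_id: str
    kind: str  # frameshift | nonsense | whole_gene_deletion | missense
    position: int | None  # gene-relative, 0-based
    support: int
    coverage: int
    fixed: bool


def _codon_index(pos: int) -> int:
    return pos // 3


def call_truncations(
    gene: GeneSequence,
    pileup: pd.DataFrame,
    min_support: int = MIN_TRUNCATION_READS,
    fixed_fraction: float = 1.0,
    species_covered_elsewhere: bool = True,
) -> list[VariantCall]:
    """Call truncating (and missense) variants for one species x gene.

    Rules: an indel whose length is not divisible by three is a
    frameshift; a substitution creating a stop codon strictly before the
    annotated terminal codon is nonsense; zero coverage at every exon
    (while the species has data at other genes) is a whole-gene
    deletion. Frameshift and nonsense calls require at least
    ``min_support`` supporting reads; a call is fixed when its
    supporting-read fraction reaches ``fixed_fraction`` (all covering
    reads, by default). Output is sorted and independent of row order.
    """
    seq = gene.sequence
    if len(seq) < 3 or len(seq) % 3 != 0:
        raise ScreenError(
            f"reference frame undefined for {gene.gene_id}: length {len(seq)}"
        )
    terminal_codon = len(seq) // 3 - 1
    rows = pileup
    species = set(rows["species"].unique())
    if len(species) > 1:
        raise ScreenError("pileup rows span several species")
    sp = species.pop() if species else "NA"

    calls: list[VariantCall] = []
    cov_rows = rows[(rows["ref"] == ".") | (rows["alt"] == ".")]
    max_depth = int(cov_rows["depth"].max()) if len(cov_rows) else 0
    if len(cov_rows) and max_depth == 0 and species_covered_elsewhere:
        calls.append(
            VariantCall(sp, gene.gene_id, "whole_gene_deletion", None, 0, 0, True)
        )

    var_rows = rows[(rows["ref"] != ".") & (rows["alt"] != ".")]
    for r in var_rows.itertuples():
        pos, ref, alt = int(r.pos), str(r.ref), str(r.alt)
        support, depth = int(r.support), int(r.depth)
        if not (0 <= pos < len(seq)):
            raise ScreenError(f"variant position {pos} outside {gene.gene_id}")
        fixed = depth > 0 and (support / depth) >= fixed_fraction
        if len(ref) != len(alt):  # indel
            if abs(len(ref) - len(alt)) % 3 == 0:
                continue  # in-frame: not truncating
            if support >= min_support:
                calls.append(
                    VariantCall(sp, gene.gene_id, "frameshift", pos, support, depth, fixed)
                )
        else:  # substitution(s)
            if len(ref) != 1:
                continue  # MNVs out of scope
            ci = _codon_index(pos)
            codon = seq[3 * ci : 3 * ci + 3]
            off = pos - 3 * ci
            mutated = codon[:off] + alt + codon[off + 1 :]
            if mutated in STOP_CODONS and ci < terminal_codon:
                if support >= min_support:
                    calls.append(
                        VariantCall(sp, gene.gene_id, "nonsense", pos, support, depth, fixed)
                    )
            elif mutated not in STOP_CODONS:
                from Bio.Seq import Seq

                if str(Seq(mutated).translate()) != str(Seq(codon).translate()):
                    calls.append(
                        VariantCall(sp, gene.gene_id, "missense", pos, support, depth, fixed)
                    )
    calls.sort(key=lambda c: (c.kind, -1 if c.position is None else c.position))
    return calls


def screen_pileups(
    pileups: pd.DataFrame,
    exon_table: pd.DataFrame,
    min_support: int = MIN_TRUNCATION_READS,
    fixed_fraction: float = 1.0,
) -> list[VariantCall]:
    """Run the truncation caller across every (species, gene) pair."""
    genes = {
        gid: assemble_gene_sequence(sub)
        for gid, sub in exon_table.groupby("gene_id", sort=False)
    }
    out: list[VariantCall] = []
    for (sp, gid), sub in pileups.groupby(["species", "gene"], sort=False):
        others = pileups[(pileups["species"] == sp) & (pileups["gene"] != gid)]
        covered_elsewhere = bool(len(others)) and int(others["depth"].max()) > 0
        out.extend(
            call_truncations(
                genes[gid],
                sub,
                min_support=min_support,
                fixed_fraction=fixed_fraction,
                species_covered_elsewhere=covered_elsewhere,
            )
        )
    return out


# ---------------------------------------------------------------------------
# clinical-site mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalSiteMatch:
    gene_id: str
    column: int  # alignment column, 0-based
    human_position: int  # 1-based human residue number
    human_residue: str
    ancestral_residue: str
    species: str
    species_residue: str
    clinical_id: str


def _column_majority(residues: list[str], threshold: float = 2 / 3) -> str | None:
    """Majority residue among non-gap outgroup states, or None."""
    res = [r for r in residues if r not in ("-", "X", ".")]
    if len(res) < 2:
        return None
    vals, counts = np.unique(res, return_counts=True)
    best = int(np.argmax(counts))
    if counts[best] / len(res) >= threshold:
        return str(vals[best])
    return None


def map_human_sites(
    alignment: dict[str, str],
    clinical: pd.DataFrame,
    gene_id: str,
    focal_species: list[str],
    outgroup_species: list[str],
    human_key: str = "human",
    majority_threshold: float = 2 / 3,
) -> list[ClinicalSiteMatch]:
    """Match species variants to human clinical-variant sites.

    Walks the protein alignment column by column. The ancestral residue
    is the >= 2/3 majority among the designated outgroup/basal species;
    columns where the ancestral state is undefined or differs from the
    human residue are skipped (the inclusion criterion). A focal-species
    residue that differs from the ancestral state and coincides with a
    clinical record (1-based human position, variant residue) yields a
    match.

    ``clinical`` columns: gene_id, position, variant_aa, clinical_id.
    """
    if human_key not in alignment:
        raise ScreenError(f"alignment lacks the human sequence {human_key!r}")
    if len(outgroup_species) < 3:
        raise ScreenError("need >= 3 outgroup species for ancestral inference")
    ncol = len(alignment[human_key])
    if any(len(s) != ncol for s in alignment.values()):
        raise ScreenError("protein alignment rows have unequal lengths")
    human_len = sum(1 for c in alignment[human_key] if c != "-")
    ctab = clinical[clinical["gene_id"] == gene_id]
    bad = ctab[(ctab["position"] < 1) | (ctab["position"] > human_len)]
    if len(bad):
        warnings.warn(
            f"{len(bad)} clinical records outside the human sequence; skipped"
        )
        ctab = ctab.drop(bad.index)
    by_pos: dict[int, list] = {}
    for r in ctab.itertuples():
        by_pos.setdefault(int(r.position), []).append(r)

    matches = []
    hpos = 0
    for col in range(ncol):
        h = alignment[human_key][col]
        if h == "-":
            continue
        hpos += 1  # 1-based human residue number
        anc = _column_majority(
            [alignment[s][col] for s in outgroup_species if s in alignment],
            majority_threshold,
        )
        if anc is None or anc != h:
            continue
        for sp in focal_species:
            if sp not in alignment:
                continue
            res = alignment[sp][col]
            if res in ("-", "X", ".") or res == anc:
                continue
            for rec in by_pos.get(hpos, []):
                if str(rec.variant_aa) == res:
                    matches.append(
                        ClinicalSiteMatch(
                            gene_id, col, hpos, h, anc, sp, res,
                            str(rec.clinical_id),
                        )
                    )
    return matches


# ---------------------------------------------------------------------------
# pleiotropy
# ---------------------------------------------------------------------------


@dataclass
class PleiotropyAnnotation:
    gene_id: str
    score: int = 0
    erythroid_biased: bool = False
    marrow_restricted: bool = False
    has_lof: bool = False


def descendants(children: dict[str, set], root: str) -> set:
    """All terms below ``root`` in the ontology (root excluded)."""
    seen: set = set()
    stack = [root]
    while stack:
        t = stack.pop()
        for c in children.get(t, ()):  # leaves simply have no entry
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return seen


def pleiotropy_score(
    gene_id: str,
    annotations: set,
    children: dict[str, set],
    hematopoietic_root: str,
    excluded_terms: set | None = None,
) -> PleiotropyAnnotation:
    """Count retained non-hematopoietic phenotype annotations.

    Everything below the hematopoietic root is removed, as are the
    explicitly excluded indirect phenotypes (pallor, blood chemistry,
    organ size, spleen abnormalities, ...) together with their
    descendants. A score of 0 means the gene has no phenotype outside
    the hematopoietic system.
    """
    all_terms = set(children)
    for kids in children.values():
        all_terms |= set(kids)
    if hematopoietic_root not in all_terms:
        raise ScreenError(f"root term {hematopoietic_root!r} not in ontology")
    unknown = {t for t in annotations if t not in all_terms}
    if unknown:
        warnings.warn(
            f"{gene_id}: {len(unknown)} annotation terms absent from the "
            "ontology; ignored"
        )
    anns = set(annotations) - unknown
    drop = descendants(children, hematopoietic_root) | {hematopoietic_root}
    for ex in excluded_terms or ():
        drop |= {ex} | descendants(children, ex)
    score = len(anns - drop)
    return PleiotropyAnnotation(gene_id=gene_id, score=score)


def classify_erythroid_bias(
    lineage_expr: pd.DataFrame,
    organ_expr: pd.DataFrame,
    erythrocyte_col: str = "erythrocyte",
    marrow_col: str = "bone_marrow",
    fold: float = 2.0,
) -> pd.DataFrame:
    """Flag erythroid-biased and marrow-restricted genes.

    A gene is erythroid-biased when its erythrocyte expression is at
    least ``fold`` times the maximum over the other hematopoietic
    lineages (and analogously marrow-restricted across organs). With
    ``fold=1.0`` the flag requires the erythrocyte to be the (weak)
    maximum. All-zero rows are flagged False with a warning.
    """
    if (lineage_expr < 0).any().any() or (organ_expr < 0).any().any():
        raise ScreenError("expression values must be >= 0")

    def flags(df, col):
        others = df.drop(columns=[col])
        other_max = others.max(axis=1)
        zero = (df.sum(axis=1) == 0)
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero expression rows")
        out = (df[col] >= fold * other_max) & ~zero
        return out

    genes = lineage_expr.index.union(organ_expr.index)
    res = pd.DataFrame(index=genes)
    res["erythroid_biased"] = flags(lineage_expr, erythrocyte_col).reindex(genes, fill_value=False)
    res["marrow_restricted"] = flags(organ_expr, marrow_col).reindex(genes, fill_value=False)
    return res


def lof_pleiotropy_association(
    annotations: list[PleiotropyAnnotation],
) -> tuple[float, float, np.ndarray]:
    """Association between zero pleiotropy and loss-of-function.

    Builds the 2x2 table {score 0, score >= 1} x {has LoF, no LoF} and
    returns (odds ratio, two-sided Fisher exact p, table). The p-value
    is the conditional hypergeometric tail (sum over tables at least as
    extreme as observed); the odds ratio uses the Haldane 0.5 correction
    when any cell is empty (reported only, not used in the test).
    """
    a = sum(1 for x in annotations if x.score == 0 and x.has_lof)
    b = sum(1 for x in annotations if x.score == 0 and not x.has_lof)
    c = sum(1 for x in annotations if x.score >= 1 and x.has_lof)
    d = sum(1 for x in annotations if x.score >= 1 and not x.has_lof)
    table = np.array([[a, b], [c, d]])
    if (a + b) == 0 or (c + d) == 0:
        raise ScreenError("need genes in both pleiotropy classes")
    if (a + c) == 0 or (b + d) == 0:
        raise ScreenError("empty margin: no variation in LoF status")
    _, p = fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        oratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = (a * d) / (b * c)
    return float(oratio), float(p), table
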