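"""Regulatory-domain assignment of conserved non-coding elements to genes.

Each gene owns a strand-aware basal window around its transcription start
site (5 kb upstream, 1 kb downstream by default). The basal window is then
extended in both directions up to a maximum (1 Mb by default), stopping
early only where it would run into another gene's *basal* window — never
at another gene's extension. A CNE is assigned to every gene whose
extended domain contains it, so assignments are many-to-many.

Coordinates are 0-based half-open (BED convention); the TSS is the 0-based
position of the first transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int

    def __post_init__(self):
        assert self.ext_start <= self.basal_start < self.basal_end <= self.ext_end


def _coerce_genes(genes) -> list[GeneModel]:
    if isinstance(genes, pd.DataFrame):
        return [
            GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in genes.itertuples()
        ]
    return list(genes)


def basal_window(
    gene: GeneModel,
    chrom_size: int,
    upstream: int = BASAL_UPSTREAM,
    downstream: int = BASAL_DOWNSTREAM,
) -> tuple[int, int]:
    """Strand-aware basal window, clipped to the chromosome."""
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    elif gene.strand == "-":
        lo, hi = gene.tss - downstream, gene.tss + upstream
    else:
        raise DomainError(f"bad strand {gene.strand!r} for {gene.gene_id}")
    return max(0, lo), min(chrom_size, hi)


def compute_domains(
    genes,
    chrom_sizes: dict[str, int],
    basal_upstream: int = BASAL_UPSTREAM,
    basal_downstream: int = BASAL_DOWNSTREAM,
    max_extension: int = MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains for a set of genes.

    The extension on each side reaches ``min(max_extension, distance to
    the nearest other gene's basal boundary)`` and never shrinks below the
    gene's own basal window.
    """
    genes = _coerce_genes(genes)
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise DomainError("duplicate gene_id")
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise DomainError(f"unknown chromosome {g.chrom!r}")
        if not (0 <= g.tss < chrom_sizes[g.chrom]):
            raise DomainError(f"tss of {g.gene_id} outside chromosome")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[RegulatoryDomain] = []
    for chrom, glist in by_chrom.items():
        size = chrom_sizes[chrom]
        basals = {
            g.gene_id: basal_window(g, size, basal_upstream, basal_downstream)
            for g in glist
        }
        for g in glist:
            b_lo, b_hi = basals[g.gene_id]
            left_stop = 0
            right_stop = size
            for other in glist:
                if other.gene_id == g.gene_id:
                    continue
                o_lo, o_hi = basals[other.gene_id]
                # a foreign basal boundary blocks extension on the side it
                # lies; overlap with the own basal clamps at the basal edge
                if o_hi <= b_lo:
                    left_stop = max(left_stop, o_hi)
                elif o_lo < b_lo:  # foreign basal overlaps from the left
                    left_stop = b_lo
                if o_lo >= b_hi:
                    right_stop = min(right_stop, o_lo)
                elif o_hi > b_hi:  # foreign basal overlaps from the right
                    right_stop = b_hi
            e_lo = max(b_lo - max_extension, left_stop, 0)
            e_hi = min(b_hi + max_extension, right_stop, size)
            e_lo = min(e_lo, b_lo)
            e_hi = max(e_hi, b_hi)
            out.append(
                RegulatoryDomain(g.gene_id, chrom, b_lo, b_hi, e_lo, e_hi)
            )
    out.sort(key=lambda d: (d.chrom, d.ext_start, d.gene_id))
    return out


def _coerce_cnes(cnes) -> list[tuple[str, str, int, int]]:
    """Accept a BED-like DataFrame or (chrom, start, end, name) records."""
    rows = []
    if isinstance(cnes, pd.DataFrame):
        for r in cnes.itertuples():
            rows.append((str(r.name), str(r.chrom), int(r.start), int(r.end)))
    else:
        for rec in cnes:
            chrom, start, end, name = rec[0], int(rec[1]), int(rec[2]), str(rec[3])
            rows.append((name, str(chrom), start, end))
    return rows


def assign_cnes(
    cnes,
    domains: list[RegulatoryDomain],
    mode: str = "midpoint",
) -> dict[str, set[str]]:
    """Map each CNE to every gene whose extended domain contains it.

    ``mode='midpoint'`` tests the CNE midpoint (half-open, so a midpoint
    exactly on a domain end is outside); ``mode='any'`` requires any
    overlap between the CNE interval and the extended domain. Returns
    ``{cne_id: set of gene_ids}`` with an (empty-set) entry for every CNE.
    """
    if mode not in ("midpoint", "any"):
        raise DomainError(f"unknown mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(
            d.ext_start, d.ext_end, d.gene_id
        )
    out: dict[str, set[str]] = {}
    warned: set[str] = set()
    for name, chrom, start, end in _coerce_cnes(cnes):
        if start >= end:
            raise DomainError(f"CNE {name} has start >= end")
        if chrom not in trees:
            if chrom not in warned:
                import warnings

                warnings.warn(f"CNE chromosome {chrom!r} has no domains")
                warned.add(chrom)
            out[name] = set()
            continue
        if mode == "midpoint":
            mid = (start + end) // 2
            hits = trees[chrom][mid]
        else:
            hits = trees[chrom].overlap(start, end)
        out[name] = {h.data for h in hits}
    return out
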