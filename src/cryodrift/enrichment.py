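"""Ontology-cluster enrichment statistics.

Three complementary statistics over gene/CNE sets:

* bootstrap Z-score of the mean per-unit score (e.g. mean foreground RER)
  against resamples of matched size from the universe;
* SUMSTAT: the sum of fourth-root LRT statistics (dlnl4) over the set,
  with an empirical bootstrap p-value;
* the high-latitude vs sub-Antarctic lineage contrast: a one-tailed
  two-sample t-test on per-branch mean RERs over the set.

p-values across terms are corrected by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection


class EnrichmentError(ValueError):
    pass


@dataclass
class OntologyTerm:
    term_id: str
    name: str = ""
    parents: frozenset = frozenset()
    genes: frozenset = frozenset()
    cnes: frozenset = frozenset()


@dataclass
class EnrichmentResult:
    term_id: str
    kind: str  # zscore | sumstat | ha_sa_t
    observed: float
    n_boot: int = 0
    p: float | None = None
    q: float | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ontology plumbing
# ---------------------------------------------------------------------------


def propagate_annotations(
    term_genes: dict[str, set], parents: dict[str, set]
) -> dict[str, set]:
    """Propagate gene annotations up the ontology DAG: a gene annotated to
    a child counts for every ancestor term."""
    out = {t: set(g) for t, g in term_genes.items()}
    # repeated relaxation is fine at this scale; DAG assumed acyclic
    changed = True
    guard = 0
    while changed:
        changed = False
        guard += 1
        if guard > 10_000:
            raise EnrichmentError("ontology parent graph appears cyclic")
        for t, ps in parents.items():
            for p in ps:
                if t in out:
                    cur = out.setdefault(p, set())
                    before = len(cur)
                    cur |= out[t]
                    if len(cur) != before:
                        changed = True
    return out


def build_terms(
    term_genes: pd.DataFrame,
    parents: pd.DataFrame | None = None,
    cne_assignment: dict[str, set] | None = None,
    names: dict[str, str] | None = None,
    propagate: bool = True,
) -> dict[str, OntologyTerm]:
    """Assemble OntologyTerm objects from long-format tables.

    ``term_genes`` has columns (term_id, gene_id); ``parents`` has
    (term_id, parent_id). With ``cne_assignment`` (cne -> genes) each
    term also gets the union of CNEs assigned to its member genes.
    """
    tg = {
        t: set(sub.gene_id)
        for t, sub in term_genes.groupby("term_id", sort=False)
    }
    par = {}
    if parents is not None:
        for r in parents.itertuples():
            par.setdefault(str(r.term_id), set()).add(str(r.parent_id))
    if propagate and par:
        tg = propagate_annotations(tg, par)
    gene_to_cnes: dict[str, set] = {}
    if cne_assignment:
        for cne, genes in cne_assignment.items():
            for g in genes:
                gene_to_cnes.setdefault(g, set()).add(cne)
    out = {}
    for t, genes in tg.items():
        cnes = frozenset().union(*(gene_to_cnes.get(g, set()) for g in genes)) if genes else frozenset()
        out[t] = OntologyTerm(
            term_id=t,
            name=(names or {}).get(t, ""),
            parents=frozenset(par.get(t, set())),
            genes=frozenset(genes),
            cnes=frozenset(cnes),
        )
    return out


def _term_units(term: OntologyTerm, unit: str) -> frozenset:
    if unit == "cne":
        return term.cnes
    if unit == "gene":
        return term.genes
    raise EnrichmentError(f"unknown resampling unit {unit!r}")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def term_zscore(
    values: pd.Series,
    term: OntologyTerm,
    n_boot: int = 1500,
    seed: int | np.random.Generator = 0,
    unit: str = "cne",
) -> EnrichmentResult:
    """Bootstrap Z-score of the term's mean score.

    ``values`` maps every unit in the universe (CNE or gene id) to a
    score. ``n_boot`` resamples of the term's size are drawn with
    replacement from the whole universe; Z is the observed mean's
    distance from the resample-mean distribution in resample-sd units.
    Positive Z = accelerated, negative = constrained.
    """
    if n_boot < 100:
        raise EnrichmentError("n_boot must be >= 100")
    units = sorted(_term_units(term, unit))
    missing = [u for u in units if u not in values.index]
    if missing:
        raise EnrichmentError(f"term units missing from values: {missing[:5]}")
    vals = values.dropna()
    term_vals = values.loc[units].dropna()
    if term_vals.empty:
        raise EnrichmentError(f"term {term.term_id} has no scored units")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pool = vals.to_numpy()
    k = len(term_vals)
    draws = rng.integers(0, len(pool), size=(n_boot, k))
    boot_means = pool[draws].mean(axis=1)
    sd = boot_means.std(ddof=1)
    obs = float(term_vals.mean())
    if sd == 0:
        return EnrichmentResult(
            term.term_id, "zscore", 0.0, n_boot, degenerate=True,
            extra={"n_units": k},
        )
    z = (obs - boot_means.mean()) / sd
    # two-sided normal p for FDR ranking across terms
    p = float(2 * stats.norm.sf(abs(z)))
    return EnrichmentResult(
        term.term_id, "zscore", float(z), n_boot, p=p,
        extra={"n_units": k, "term_mean": obs},
    )


def sumstat_enrichment(
    results: pd.DataFrame,
    term: OntologyTerm,
    n_boot: int = 1500,
    seed: int | np.random.Generator = 0,
    unit: str = "cne",
    value_col: str = "delta_lnl4",
    id_col: str = "element_id",
) -> EnrichmentResult:
    """SUMSTAT enrichment of summed fourth-root LRT statistics.

    The observed statistic is the sum of ``delta_lnl4`` over the term's
    units; the empirical p-value is ``(1 + #{resample sums >= observed})
    / (1 + n_boot)`` with resamples of the term's size drawn with
    replacement from the universe, so p is never exactly zero.
    """
    if n_boot < 100:
        raise EnrichmentError("n_boot must be >= 100")
    scores = results.set_index(id_col)[value_col]
    units = sorted(_term_units(term, unit))
    missing = [u for u in units if u not in scores.index]
    if missing:
        raise EnrichmentError(
            f"term {term.term_id} units absent from results: {missing[:5]}"
        )
    term_scores = scores.loc[units].dropna()
    pool = scores.dropna().to_numpy()
    k = len(term_scores)
    if k == 0:
        raise EnrichmentError(f"term {term.term_id} has no scored units")
    obs = float(term_scores.sum())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = rng.integers(0, len(pool), size=(n_boot, k))
    sums = pool[draws].sum(axis=1)
    n_ge = int(np.sum(sums >= obs - 1e-12))
    p = (1 + n_ge) / (1 + n_boot)
    return EnrichmentResult(
        term.term_id, "sumstat", obs, n_boot, p=float(p),
        extra={"n_units": k},
    )


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    _, q = fdrcorrection(p, alpha=0.05, method="indep")
    return q


def ha_sa_contrast(
    rer,
    term: OntologyTerm,
    tip_classes: dict[str, str] | None = None,
    welch: bool = False,
) -> EnrichmentResult:
    """One-tailed HA > SA contrast of extant-lineage mean RERs.

    For every extant (tip) branch classified HA or SA, the branch's RERs
    are averaged over the term's CNE loci; the two groups of per-branch
    means are compared with a one-tailed two-sample t-test (equal
    variance by default, Welch optional).
    """
    table = rer.table if hasattr(rer, "table") else rer
    meta = rer.branch_meta if hasattr(rer, "branch_meta") else None
    if tip_classes is None:
        if meta is None:
            raise EnrichmentError("tip classes required")
        tip_classes = meta.tip_class.to_dict()
    if meta is not None:
        tips = set(meta.index[meta.is_tip])
    else:
        tips = set(table.columns)
    loci = sorted(term.cnes & set(table.index))
    if not loci:
        raise EnrichmentError(f"term {term.term_id} matches no RER loci")
    sub = table.loc[loci]
    groups = {"HA": [], "SA": []}
    for b in table.columns:
        cls = tip_classes.get(b)
        if b in tips and cls in groups:
            m = float(sub[b].mean())
            if np.isfinite(m):
                groups[cls].append(m)
    ha, sa = np.array(groups["HA"]), np.array(groups["SA"])
    if len(ha) < 2 or len(sa) < 2:
        raise EnrichmentError("need >= 2 observed branches per class")
    import warnings as _w

    with _w.catch_warnings():
        # identical groups trip a scipy precision warning; handled below
        _w.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(ha, sa, equal_var=not welch, alternative="greater")
    if not np.isfinite(t):  # zero pooled variance
        t, p = 0.0, 0.5
    return EnrichmentResult(
        term.term_id, "ha_sa_t", float(t), p=float(p),
        extra={"n_ha": len(ha), "n_sa": len(sa)},
    )


def attach_q_values(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """FDR-correct a family of results in place (input order kept)."""
    ps = [r.p for r in results]
    if any(p is None for p in ps):
        raise EnrichmentError("all results need p-values before FDR")
    qs = fdr_correct(ps)
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
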