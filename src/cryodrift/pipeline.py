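"""End-to-end driver: synthetic data -> RER + acceleration -> enrichment.

Chains the full analysis on one simulated dataset: fit the neutral model
on (a subsample of) the elements, estimate per-locus branch lengths,
compute RERs, run the foreground acceleration scan, assign CNEs to gene
regulatory domains, build ontology terms, and score every term with the
bootstrap Z and SUMSTAT statistics plus FDR. Used by the validation
suite and by the reproduction script; also handy interactively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import domains as dom
from .acceleration import accel_scan
from .enrichment import (
    attach_q_values,
    build_terms,
    sumstat_enrichment,
    term_zscore,
)
from .phylo import TreeModel, estimate_branch_lengths, fit_neutral_model
from .rer import RERMatrix, build_branch_matrix, compute_rer
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_annotation_set,
    simulate_loci,
    simulate_tree,
)


@dataclass
class PlantedAnalysis:
    """Everything the end-to-end run produces."""

    tree: TreeModel
    neutral: TreeModel
    truth: GroundTruth
    rer: RERMatrix
    accel: pd.DataFrame
    term_table: pd.DataFrame  # term_id, n_cnes, zscore, sumstat p/q
    assignment: dict = field(default_factory=dict)

    @property
    def planted_term_id(self):
        return self.truth.planted_term_id

    def planted_row(self) -> pd.Series:
        return self.term_table.set_index("term_id").loc[self.planted_term_id]


def run_planted_analysis(
    config: SimulationConfig,
    n_boot: int = 1500,
    neutral_subsample: int = 60,
    min_term_cnes: int = 5,
    rer_fit_kwargs: dict | None = None,
) -> PlantedAnalysis:
    """Simulate one dataset under ``config`` and run the whole pipeline.

    ``neutral_subsample`` elements (deterministically, the first by id)
    are concatenated for the neutral-model fit; ``min_term_cnes`` is the
    desk-scale analogue of the minimum-term-size rule (1,000 CNEs at
    genome scale). Bootstrap seeds derive from ``config.seed``.
    """
    rer_fit_kwargs = dict(rer_fit_kwargs or {"rtol": 1e-4, "max_sweeps": 8})
    tree = simulate_tree(config)
    loci, truth = simulate_loci(tree, config)
    genes, cnes, term_genes, parents = simulate_annotation_set(config, truth)

    sub_ids = sorted(loci)[:neutral_subsample]
    neutral = fit_neutral_model(
        {k: loci[k] for k in sub_ids},
        tree,
        min_length=min(250, config.locus_length),
    )

    fits = [
        estimate_branch_lengths(aln, neutral, locus_id=lid, **rer_fit_kwargs)
        for lid, aln in loci.items()
    ]
    matrix = build_branch_matrix(fits, neutral)
    rer = compute_rer(matrix)

    accel = accel_scan(loci, neutral, tree.foreground_branch)

    domain_list = dom.compute_domains(genes, {"chr1": config.genome_length})
    assignment = dom.assign_cnes(cnes, domain_list)
    terms = build_terms(term_genes, parents, cne_assignment=assignment)
    terms.pop("T_ROOT", None)

    fg_rer = rer.foreground_series()
    boot_rng = np.random.default_rng([config.seed, 99])
    rows = []
    z_results, s_results = [], []
    for tid in sorted(terms):
        term = terms[tid]
        if len(term.cnes) < min_term_cnes:
            continue
        z = term_zscore(fg_rer, term, n_boot=n_boot, seed=boot_rng)
        s = sumstat_enrichment(accel, term, n_boot=n_boot, seed=boot_rng)
        z_results.append(z)
        s_results.append(s)
        rows.append(
            {
                "term_id": tid,
                "n_cnes": len(term.cnes),
                "n_genes": len(term.genes),
                "zscore": z.observed,
                "z_p": z.p,
                "sumstat": s.observed,
                "sumstat_p": s.p,
            }
        )
    attach_q_values(s_results)
    attach_q_values(z_results)
    table = pd.DataFrame(rows)
    table["sumstat_q"] = [r.q for r in s_results]
    table["z_q"] = [r.q for r in z_results]
    return PlantedAnalysis(
        tree=tree,
        neutral=neutral,
        truth=truth,
        rer=rer,
        accel=accel,
        term_table=table,
        assignment=assignment,
    )
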