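"""Shared fixtures: small trees, simulated alignments, and oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cryodrift.phylo import STATES, SubstitutionModel, TreeModel


def random_tree_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Random binary topology with uniform-ish branch lengths."""
    nodes = [f"t{i}:{rng.uniform(0.01, 0.5):.4f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.01, 0.5):.4f}")
    return nodes[0].rsplit(":", 1)[0] + ";"


def evolve(tree: TreeModel, n_sites: int, rng, branch_scales=None) -> dict[str, str]:
    """Forward-simulate an alignment on a tree (test-local copy)."""
    idx = tree.index()
    model = tree.model
    scales = branch_scales or {}
    states = {idx.root: rng.choice(4, size=n_sites, p=model.freqs)}
    for v in reversed(idx.postorder):
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


def brute_force_loglik(seqs: dict[str, str], tm: TreeModel) -> float:
    """Exhaustive enumeration over all internal-state assignments.

    Independent oracle for the pruning algorithm; exponential in the
    number of internal nodes, so only usable on tiny trees.
    """
    idx = tm.index()
    model = tm.model
    internal = [v for v in idx.postorder if not idx.is_tip[v]]
    pmats = {v: model.transition_matrix(idx.blen[v]) for v in idx.branch_nodes}
    n = len(next(iter(seqs.values())))
    ll = 0.0
    for site in range(n):
        tot = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            st = dict(zip(internal, assign))
            pr = model.freqs[st[idx.root]]
            for v in idx.branch_nodes:
                pv = st[idx.parent[v]]
                if idx.is_tip[v]:
                    c = seqs[idx.tip_label[v]][site]
                    if c in STATES:
                        pr *= pmats[v][pv, STATES.index(c)]
                    # gap/N: sum over tip states = 1, contributes factor 1
                else:
                    pr *= pmats[v][pv, st[v]]
            tot += pr
        ll += np.log(tot)
    return ll


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def jc_pair():
    """Two-taxon JC tree with total path length 0.3."""
    return TreeModel.from_newick("(a:0.15,b:0.15);", SubstitutionModel.jc())


@pytest.fixture
def five_taxon_hky():
    nw = "((a:0.1,b:0.2):0.07,((c:0.15,d:0.08):0.1,e:0.3):0.05);"
    model = SubstitutionModel.hky([0.3, 0.2, 0.3, 0.2], kappa=3.0)
    return TreeModel.from_newick(nw, model)
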