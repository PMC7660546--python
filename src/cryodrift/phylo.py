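"""Phylogenetic likelihood machinery on a fixed species topology.

This module implements the core of the comparative pipeline: nucleotide
substitution models (JC and HKY), Felsenstein-pruning log-likelihoods,
joint fitting of a neutral model on filtered concatenated elements, and
per-locus branch-length estimation with the model held fixed.

Conventions
-----------
* Branch lengths are expected substitutions per site and every non-root
  node owns the branch to its parent; a branch is identified by the label
  of its child node (tip labels for terminal branches, internal node
  labels otherwise).
* Alignment columns over ``{A, C, G, T}``; gaps, ``N`` and any other
  ambiguity code are treated as missing data (partial likelihood one for
  every state).
* A species absent from an alignment is marginalised out rather than
  pruned, so the topology is identical across loci; branches that are
  unidentifiable for a given locus are reported as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

STATES = "ACGT"
STATE_INDEX = {c: i for i, c in enumerate(STATES)}
MISSING_CODE = 4  # gap / N / any ambiguity
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T

DEFAULT_BRANCH_CAP = 10.0
_RESCALE_FLOOR = 1e-100


class PhyloError(ValueError):
    """Raised for invalid alignments, trees or model configurations."""


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------


class SubstitutionModel:
    """Time-reversible nucleotide model with unit expected substitution rate.

    Parameters
    ----------
    freqs : array-like of 4 floats
        Equilibrium frequencies (A, C, G, T); must sum to 1.
    kappa : float
        Transition/transversion rate ratio. ``kappa=1`` with uniform
        frequencies recovers Jukes-Cantor.
    name : str
        Display name.
    """

    def __init__(self, freqs, kappa: float = 1.0, name: str = "HKY"):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise PhyloError("freqs must be four positive values")
        if not np.isclose(freqs.sum(), 1.0, atol=1e-8):
            raise PhyloError("freqs must sum to 1")
        if kappa <= 0:
            raise PhyloError("kappa must be positive")
        self.freqs = freqs / freqs.sum()
        self.kappa = float(kappa)
        self.name = name
        self._build()

    def _build(self) -> None:
        pi = self.freqs
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = self.kappa if (i, j) in _TRANSITIONS else 1.0
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to one expected substitution per unit time
        mu = -np.dot(pi, np.diag(q))
        q /= mu
        self.Q = q
        # reversible model: symmetrise and eigendecompose once
        d = np.sqrt(pi)
        sym = (q * d[:, None]) / d[None, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self._eigval = w
        self._left = u / d[:, None]
        self._right = u.T * d[None, :]

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        return cls(np.full(4, 0.25), kappa=1.0, name="JC")

    @classmethod
    def hky(cls, freqs, kappa: float) -> "SubstitutionModel":
        return cls(freqs, kappa=kappa, name="HKY")

    def with_kappa(self, kappa: float) -> "SubstitutionModel":
        return SubstitutionModel(self.freqs, kappa=kappa, name=self.name)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows index the parent state."""
        if t < 0:
            raise PhyloError("branch length must be non-negative")
        p = (self._left * np.exp(self._eigval * t)) @ self._right
        np.maximum(p, 0.0, out=p)
        return p

    def transition_matrix_with_derivative(self, t: float):
        """P(t) and dP/dt, via the cached eigendecomposition."""
        ew = np.exp(self._eigval * t)
        p = (self._left * ew) @ self._right
        dp = (self._left * (self._eigval * ew)) @ self._right
        np.maximum(p, 0.0, out=p)
        return p, dp


# ---------------------------------------------------------------------------
# tree model
# ---------------------------------------------------------------------------


class TreeModel:
    """A rooted tree with branch lengths, a substitution model and labels.

    Wraps a :class:`dendropy.Tree`. Internal nodes without labels are
    auto-labelled ``i<k>`` in postorder so that every branch has a stable
    identifier.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        model: SubstitutionModel | None = None,
        foreground_branch: str | None = None,
        tip_classes: dict[str, str] | None = None,
    ):
        self.tree = tree
        self.model = model if model is not None else SubstitutionModel.hky(
            np.full(4, 0.25), kappa=2.0
        )
        self._label_nodes()
        ids = self.branch_ids()
        if len(ids) != len(set(ids)):
            raise PhyloError("branch labels are not unique")
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                node.edge.length = 0.0
            if not np.isfinite(node.edge.length) or node.edge.length < 0:
                raise PhyloError("branch lengths must be finite and >= 0")
        if foreground_branch is not None and foreground_branch not in set(ids):
            raise PhyloError(
                f"foreground branch {foreground_branch!r} not in tree"
            )
        self.foreground_branch = foreground_branch
        self.tip_classes = dict(tip_classes or {})
        self._index: _TreeIndex | None = None

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        model: SubstitutionModel | None = None,
        foreground_branch: str | None = None,
        tip_classes: dict[str, str] | None = None,
    ) -> "TreeModel":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False
        )
        return cls(tree, model, foreground_branch, tip_classes)

    def _label_nodes(self) -> None:
        k = 0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None:
                    raise PhyloError("leaf without taxon label")
                continue
            label = node.label or (node.taxon.label if node.taxon else None)
            if not label:
                node.label = f"i{k}"
            k += 1

    # -- accessors -----------------------------------------------------------

    @staticmethod
    def _node_branch_id(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return node.label

    def branch_ids(self) -> list[str]:
        """Branch identifiers in postorder (root excluded)."""
        return [
            self._node_branch_id(n)
            for n in self.tree.postorder_node_iter()
            if n.parent_node is not None
        ]

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def branch_lengths(self) -> dict[str, float]:
        return {
            self._node_branch_id(n): float(n.edge.length)
            for n in self.tree.postorder_node_iter()
            if n.parent_node is not None
        }

    def set_branch_lengths(self, lengths: dict[str, float]) -> None:
        for node in self.tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            bid = self._node_branch_id(node)
            if bid in lengths:
                node.edge.length = float(lengths[bid])
        self._index = None

    def clade_tips(self, branch_id: str) -> set[str]:
        """Tip labels below the given branch."""
        for node in self.tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            if self._node_branch_id(node) == branch_id:
                return {l.taxon.label for l in node.leaf_iter()}
        raise PhyloError(f"no branch {branch_id!r}")

    def is_terminal(self, branch_id: str) -> bool:
        return branch_id in set(self.tip_labels())

    def clone(self) -> "TreeModel":
        return TreeModel(
            self.tree.clone(depth=1),
            self.model,
            self.foreground_branch,
            dict(self.tip_classes),
        )

    def as_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                suppress_internal_node_labels=False,
            ).strip()
            + "\n"
        )

    def index(self) -> "_TreeIndex":
        if self._index is None:
            self._index = _TreeIndex(self)
        return self._index


# ---------------------------------------------------------------------------
# flat index used by the pruning engine
# ---------------------------------------------------------------------------


class _TreeIndex:
    """Array view of a TreeModel for fast likelihood passes."""

    def __init__(self, tm: TreeModel):
        nodes = list(tm.tree.postorder_node_iter())
        self.n = len(nodes)
        self.node_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.blen = np.zeros(self.n)
        self.branch_id: list[str | None] = [None] * self.n
        self.is_tip = np.zeros(self.n, dtype=bool)
        self.tip_label: list[str | None] = [None] * self.n
        self.postorder: list[int] = []
        for i, nd in enumerate(nodes):
            self.postorder.append(i)
            if nd.parent_node is not None:
                p = self.node_of[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.blen[i] = float(nd.edge.length or 0.0)
                self.branch_id[i] = TreeModel._node_branch_id(nd)
            if nd.is_leaf():
                self.is_tip[i] = True
                self.tip_label[i] = nd.taxon.label
        self.root = self.postorder[-1]
        self.branch_nodes = [i for i in self.postorder if i != self.root]
        self.node_by_branch = {
            self.branch_id[i]: i for i in self.branch_nodes
        }
        # number of tips below each node (for identifiability bookkeeping)
        self.tips_below = np.zeros(self.n, dtype=int)
        for i in self.postorder:
            if self.is_tip[i]:
                self.tips_below[i] = 1
            else:
                self.tips_below[i] = sum(
                    self.tips_below[c] for c in self.children[i]
                )


# ---------------------------------------------------------------------------
# alignment handling
# ---------------------------------------------------------------------------


def _as_sequence_dict(alignment) -> dict[str, str]:
    """Accept {name: seq} mappings or Biopython alignments/records."""
    if isinstance(alignment, dict):
        return {str(k): str(v).upper() for k, v in alignment.items()}
    out = {}
    for rec in alignment:  # MultipleSeqAlignment or iterable of SeqRecords
        out[rec.id] = str(rec.seq).upper()
    return out


def encode_alignment(alignment, idx: _TreeIndex):
    """Compress an alignment into unique site patterns on the tree's tips.

    Returns ``(codes, weights, observed)`` where ``codes`` is an
    ``(n_tips_on_tree, n_patterns)`` integer array with 0-3 for ACGT and 4
    for missing, ``weights`` the pattern multiplicities and ``observed``
    a boolean mask (per tree tip) of species present in the alignment.
    """
    seqs = _as_sequence_dict(alignment)
    if not seqs:
        raise PhyloError("empty alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise PhyloError("alignment rows have unequal lengths")
    (n_sites,) = lengths
    if n_sites == 0:
        raise PhyloError("alignment has zero columns")
    tip_nodes = [i for i in range(idx.n) if idx.is_tip[i]]
    tree_tips = [idx.tip_label[i] for i in tip_nodes]
    unknown = set(seqs) - set(tree_tips)
    if unknown:
        raise PhyloError(f"alignment taxa not in tree: {sorted(unknown)}")
    lut = np.full(256, MISSING_CODE, dtype=np.int8)
    for c, i in STATE_INDEX.items():
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    rows = []
    observed = np.zeros(len(tip_nodes), dtype=bool)
    for k, label in enumerate(tree_tips):
        if label in seqs:
            observed[k] = True
            rows.append(lut[np.frombuffer(seqs[label].encode(), dtype=np.uint8)])
        else:
            rows.append(np.full(n_sites, MISSING_CODE, dtype=np.int8))
    mat = np.vstack(rows)
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float), observed, tip_nodes


def _tip_partials(patterns, tip_nodes, idx):
    """Per-tip partial likelihood arrays, (n_patterns, 4) each."""
    npat = patterns.shape[1]
    eye = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing
    parts = {}
    for k, node in enumerate(tip_nodes):
        parts[node] = eye[patterns[k]]
    return parts, npat


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def _branch_length_vector(idx: _TreeIndex, scales=None) -> np.ndarray:
    t = idx.blen.copy()
    if scales:
        for bid, s in scales.items():
            if bid not in idx.node_by_branch:
                raise PhyloError(f"unknown branch {bid!r} in scales")
            if s <= 0:
                raise PhyloError("branch scales must be positive")
            t[idx.node_by_branch[bid]] *= s
    return t


def _postorder_down(idx, model, t, tip_parts, npat):
    """Post-order pass: per-node subtree partials with per-pattern rescaling.

    Returns (down, dscale, msg, mscale): ``down[v]`` is the partial of the
    subtree below v conditional on the state at v; ``msg[v]`` is the
    message across v's parent edge, i.e. ``down[v] @ P(t_v).T``.
    """
    down = [None] * idx.n
    dscale = [None] * idx.n
    msg = [None] * idx.n
    mscale = [None] * idx.n
    for v in idx.postorder:
        if idx.is_tip[v]:
            down[v] = tip_parts[v]
            dscale[v] = np.zeros(npat)
        else:
            acc = np.ones((npat, 4))
            sc = np.zeros(npat)
            for c in idx.children[v]:
                acc = acc * msg[c]
                sc = sc + mscale[c]
            # rescale to dodge underflow on deep trees
            mx = acc.max(axis=1)
            bad = mx < _RESCALE_FLOOR
            if bad.any():
                f = np.where(bad & (mx > 0), mx, 1.0)
                acc = acc / f[:, None]
                sc = sc + np.log(f)
            down[v] = acc
            dscale[v] = sc
        if v != idx.root:
            p = model.transition_matrix(t[v])
            msg[v] = down[v] @ p.T
            mscale[v] = dscale[v]
    return down, dscale, msg, mscale


def _root_loglik(idx, model, down, dscale, weights):
    site = down[idx.root] @ model.freqs
    if np.any(site <= 0):
        return -np.inf
    return float(np.dot(weights, np.log(site) + dscale[idx.root]))


def prune_loglik(alignment, tree: TreeModel, branch_scales=None) -> float:
    """Felsenstein-pruning log-likelihood of an alignment on a tree.

    Each branch length may be multiplied by a positive scale factor via
    ``branch_scales`` (mapping branch id -> scale); unlisted branches use
    scale 1. Gap/N columns contribute partial likelihood one.
    """
    idx = tree.index()
    patterns, weights, _, tip_nodes = encode_alignment(alignment, idx)
    tip_parts, npat = _tip_partials(patterns, tip_nodes, idx)
    t = _branch_length_vector(idx, branch_scales)
    down, dscale, _, _ = _postorder_down(
        idx, tree.model, t, tip_parts, npat
    )
    return _root_loglik(idx, tree.model, down, dscale, weights)


def _preorder_context(idx, model, t, down, dscale, msg, mscale, npat):
    """Pre-order pass computing, per non-root node v, the likelihood
    context of the rest of the tree seen from v's parent (state indexed at
    the parent, root prior folded in)."""
    ctx = [None] * idx.n
    cscale = [None] * idx.n
    edge_ctx = [None] * idx.n
    edge_scale = [None] * idx.n
    ctx[idx.root] = np.broadcast_to(model.freqs, (npat, 4)).copy()
    cscale[idx.root] = np.zeros(npat)
    for v in reversed(idx.postorder):  # preorder
        if idx.is_tip[v]:
            continue
        kids = idx.children[v]
        # prefix/suffix products of sibling messages
        k = len(kids)
        pref = [None] * (k + 1)
        pref_s = [None] * (k + 1)
        pref[0] = np.ones((npat, 4))
        pref_s[0] = np.zeros(npat)
        for i, c in enumerate(kids):
            pref[i + 1] = pref[i] * msg[c]
            pref_s[i + 1] = pref_s[i] + mscale[c]
        suf = np.ones((npat, 4))
        suf_s = np.zeros(npat)
        for i in range(k - 1, -1, -1):
            c = kids[i]
            e = ctx[v] * pref[i] * suf
            es = cscale[v] + pref_s[i] + suf_s
            mx = e.max(axis=1)
            bad = mx < _RESCALE_FLOOR
            if bad.any():
                f = np.where(bad & (mx > 0), mx, 1.0)
                e = e / f[:, None]
                es = es + np.log(f)
            edge_ctx[c] = e
            edge_scale[c] = es
            p = model.transition_matrix(t[c])
            ctx[c] = e @ p
            cscale[c] = es
            suf = suf * msg[c]
            suf_s = suf_s + mscale[c]
    return edge_ctx, edge_scale


def _edge_loglik(edge_ctx, edge_scale, down_v, dscale_v, weights, model, t):
    """Log-likelihood as a function of one branch length, everything else
    frozen: sum_patterns w * log( ctx . P(t) . down )."""
    p = model.transition_matrix(t)
    site = ((edge_ctx @ p) * down_v).sum(axis=1)
    if site.min() <= 0:
        return -np.inf
    return float(np.dot(weights, np.log(site) + edge_scale + dscale_v))


def _optimize_edge(edge_ctx, down_v, weights, model, t0, cap):
    """Maximise the single-edge log-likelihood over t in [0, cap].

    Root-finds the score (d lnL / dt) with Brent's method; the score is
    computed from the eigendecomposition so each evaluation costs two
    small matrix products.
    """
    from scipy.optimize import brentq

    def score(x):
        p, dp = model.transition_matrix_with_derivative(x)
        site = ((edge_ctx @ p) * down_v).sum(axis=1)
        dsite = ((edge_ctx @ dp) * down_v).sum(axis=1)
        site = np.maximum(site, 1e-300)
        return float(np.dot(weights, dsite / site))

    lo = 1e-9
    if score(lo) <= 0:
        return 0.0, False
    hi = max(min(t0, cap), 0.05)
    d_hi = score(hi)
    while d_hi > 0 and hi < cap:
        hi = min(hi * 4.0, cap)
        d_hi = score(hi)
    if d_hi > 0:
        return cap, True
    return float(brentq(score, lo, hi, xtol=1e-7, rtol=1e-8)), False


@dataclass
class LocusBranchLengths:
    """Per-locus branch length estimates on the master topology."""

    locus_id: str
    lengths: dict[str, float]  # branch id -> length; NaN when missing
    n_sites: int
    converged: bool
    loglik: float = float("nan")
    hit_cap: frozenset = frozenset()  # branches stuck at the length cap

    def as_array(self, branch_ids: list[str]) -> np.ndarray:
        return np.array([self.lengths.get(b, np.nan) for b in branch_ids])


def _identifiable_branches(idx, observed_tips: set[int]) -> set[int]:
    """Branches with observed tips on both sides of the edge."""
    n_obs = len(observed_tips)
    obs_below = np.zeros(idx.n, dtype=int)
    for v in idx.postorder:
        if idx.is_tip[v]:
            obs_below[v] = 1 if v in observed_tips else 0
        else:
            obs_below[v] = sum(obs_below[c] for c in idx.children[v])
    keep = set()
    for v in idx.branch_nodes:
        if 0 < obs_below[v] < n_obs:
            keep.add(v)
    return keep


def estimate_branch_lengths(
    alignment,
    tree: TreeModel,
    model: SubstitutionModel | None = None,
    locus_id: str = "",
    max_branch_length: float = DEFAULT_BRANCH_CAP,
    min_sweeps: int = 2,
    max_sweeps: int = 25,
    rtol: float = 1e-5,
) -> LocusBranchLengths:
    """Maximum-likelihood branch lengths for one locus, model fixed.

    Coordinate-wise bounded scalar optimisation: each sweep refreshes the
    outside-the-edge context vectors, then optimises every branch in
    postorder with subtree partials updated as the sweep ascends. At
    least ``min_sweeps`` sweeps are run; convergence is declared when a
    sweep improves the log-likelihood by less than ``rtol`` relative to
    one unit (and no branch moved by more than ``sqrt(rtol)``).
    """
    model = model or tree.model
    idx = tree.index()
    patterns, weights, observed, tip_nodes = encode_alignment(alignment, idx)
    tip_parts, npat = _tip_partials(patterns, tip_nodes, idx)
    observed_tips = {n for n, o in zip(tip_nodes, observed) if o}
    estimable = _identifiable_branches(idx, observed_tips)

    t = np.minimum(idx.blen.copy(), max_branch_length)
    t[t <= 0] = 0.01  # benign start for zero-length inputs
    for v in idx.branch_nodes:
        if v not in estimable:
            t[v] = 0.0

    # messages kept consistent with the current length vector throughout,
    # so each 1-D step is exact coordinate ascent and lnL is monotone
    down, dscale, msg, mscale = _postorder_down(idx, model, t, tip_parts, npat)

    def refresh_down(v):
        acc = np.ones((npat, 4))
        sc = np.zeros(npat)
        for c in idx.children[v]:
            acc = acc * msg[c]
            sc = sc + mscale[c]
        mx = acc.max(axis=1)
        bad = mx < _RESCALE_FLOOR
        if bad.any():
            f = np.where(bad & (mx > 0), mx, 1.0)
            acc = acc / f[:, None]
            sc = sc + np.log(f)
        down[v] = acc
        dscale[v] = sc

    def refresh_msg(v):
        p = model.transition_matrix(t[v])
        msg[v] = down[v] @ p.T
        mscale[v] = dscale[v]

    state = {"max_rel": 0.0, "capped": set()}

    def visit(u, ctx_u, cscale_u):
        kids = idx.children[u]
        for v in kids:
            e = ctx_u.copy()
            es = cscale_u.copy()
            for s in kids:
                if s != v:
                    e = e * msg[s]
                    es = es + mscale[s]
            mx = e.max(axis=1)
            bad = mx < _RESCALE_FLOOR
            if bad.any():
                f = np.where(bad & (mx > 0), mx, 1.0)
                e = e / f[:, None]
                es = es + np.log(f)
            if v in estimable:
                new, capped = _optimize_edge(
                    e, down[v], weights, model, t[v], max_branch_length
                )
                if capped:
                    state["capped"].add(idx.branch_id[v])
                else:
                    state["capped"].discard(idx.branch_id[v])
                denom = max(t[v], new, 1e-12)
                state["max_rel"] = max(
                    state["max_rel"], abs(new - t[v]) / denom
                )
                t[v] = new
                refresh_msg(v)
            if not idx.is_tip[v]:
                p = model.transition_matrix(t[v])
                visit(v, e @ p, es)
                refresh_down(v)
                refresh_msg(v)

    converged = False
    last_ll = -np.inf
    root_ctx = np.broadcast_to(model.freqs, (npat, 4)).copy()
    root_scale = np.zeros(npat)
    for sweep in range(max_sweeps):
        state["max_rel"] = 0.0
        visit(idx.root, root_ctx, root_scale)
        refresh_down(idx.root)
        ll = _root_loglik(idx, model, down, dscale, weights)
        if sweep + 1 >= min_sweeps and ll - last_ll < rtol:
            converged = True
            last_ll = ll
            break
        last_ll = ll

    refresh_down(idx.root)
    ll = _root_loglik(idx, model, down, dscale, weights)
    lengths = {}
    for v in idx.branch_nodes:
        bid = idx.branch_id[v]
        lengths[bid] = float(t[v]) if v in estimable else float("nan")
    return LocusBranchLengths(
        locus_id=locus_id,
        lengths=lengths,
        n_sites=int(weights.sum()),
        converged=converged and not state["capped"],
        loglik=ll,
        hit_cap=frozenset(state["capped"]),
    )


# ---------------------------------------------------------------------------
# neutral model fitting
# ---------------------------------------------------------------------------


def _coverage_ok(seqs: dict[str, str], species: list[str], min_coverage: float):
    n = len(next(iter(seqs.values())))
    for sp in species:
        if sp not in seqs:
            return False
        s = seqs[sp]
        nongap = sum(1 for c in s.upper() if c in STATE_INDEX)
        if nongap / n < min_coverage:
            return False
    return True


def filter_elements(
    elements: dict[str, object],
    tree: TreeModel,
    min_length: int = 250,
    min_coverage: float = 0.85,
):
    """Apply the neutral-model element filters.

    Elements shorter than ``min_length`` or with any species below
    ``min_coverage`` non-gap coverage are excluded. Returns the surviving
    ids plus per-filter rejection counts.
    """
    species = tree.tip_labels()
    kept, n_short, n_cov = [], 0, 0
    for eid, aln in elements.items():
        seqs = _as_sequence_dict(aln)
        length = len(next(iter(seqs.values())))
        if length < min_length:
            n_short += 1
            continue
        if not _coverage_ok(seqs, species, min_coverage):
            n_cov += 1
            continue
        kept.append(eid)
    return kept, {"too_short": n_short, "low_coverage": n_cov}


def concatenate_alignments(elements: dict[str, object], species: list[str]):
    parts = {sp: [] for sp in species}
    for aln in elements.values():
        seqs = _as_sequence_dict(aln)
        n = len(next(iter(seqs.values())))
        for sp in species:
            parts[sp].append(seqs.get(sp, "-" * n))
    return {sp: "".join(chunks) for sp, chunks in parts.items()}


def empirical_frequencies(seqs: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs.values():
        arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
        for c, i in STATE_INDEX.items():
            counts[i] += int((arr == ord(c)).sum())
    if counts.sum() == 0:
        raise PhyloError("no resolved bases in concatenated elements")
    # tiny pseudocount keeps all frequencies positive
    counts += 0.5
    return counts / counts.sum()


def fit_neutral_model(
    elements: dict[str, object],
    tree: TreeModel,
    min_length: int = 250,
    min_coverage: float = 0.85,
    model_family: str = "hky",
    max_branch_length: float = DEFAULT_BRANCH_CAP,
    outer_iters: int = 6,
    kappa_bounds: tuple[float, float] = (0.05, 50.0),
) -> TreeModel:
    """Fit the neutral tree model on filtered, concatenated elements.

    Elements are filtered (``min_length`` bp, ``min_coverage`` per-species
    non-gap coverage), survivors concatenated, and branch lengths plus
    model parameters (kappa for HKY; base frequencies taken empirically)
    jointly maximise the pruning likelihood by alternating branch sweeps
    with bounded 1-D kappa optimisation.
    """
    kept, drops = filter_elements(elements, tree, min_length, min_coverage)
    if not kept:
        raise PhyloError(
            "no element passed the neutral-model filters "
            f"(too_short={drops['too_short']}, low_coverage={drops['low_coverage']})"
        )
    species = tree.tip_labels()
    concat = concatenate_alignments({k: elements[k] for k in kept}, species)

    if model_family.lower() == "jc":
        model = SubstitutionModel.jc()
    elif model_family.lower() == "hky":
        model = SubstitutionModel.hky(empirical_frequencies(concat), kappa=2.0)
    else:
        raise PhyloError(f"unknown model family {model_family!r}")

    work = tree.clone()
    last_ll = -np.inf
    for _ in range(outer_iters):
        fit = estimate_branch_lengths(
            concat, work, model=model, max_branch_length=max_branch_length,
            min_sweeps=2, max_sweeps=10,
        )
        work.set_branch_lengths(fit.lengths)
        if model_family.lower() == "hky":
            def nll_kappa(logk):
                m = model.with_kappa(float(np.exp(logk)))
                return -prune_loglik(concat, TreeModel(
                    work.tree, m, work.foreground_branch, work.tip_classes
                ))

            res = minimize_scalar(
                nll_kappa,
                bounds=tuple(np.log(kappa_bounds)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            model = model.with_kappa(float(np.exp(res.x)))
            ll = -res.fun
        else:
            ll = fit.loglik
        if np.isfinite(last_ll) and abs(ll - last_ll) < 1e-4:
            last_ll = ll
            break
        last_ll = ll

    fitted = TreeModel(
        work.tree, model, tree.foreground_branch, dict(tree.tip_classes)
    )
    fitted.n_elements_used = len(kept)
    fitted.filter_drops = drops
    fitted.loglik = last_ll
    return fitted
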