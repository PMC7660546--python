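"""Relative evolutionary rates (RER) per branch per locus.

A locus tree that is simply a rescaled copy of the genome-wide average
tree carries no rate information; what matters is how much each branch
deviates from its genome-wide expectation *given* the locus's overall
rate. RERs capture exactly that: per-locus branch lengths are scaled,
transformed, regressed on the master expectation, and the (weighted,
standardised) residuals are the relative rates — positive means the
branch evolved faster than expected at that locus, negative slower.

The weighting step corrects the strong variance-mean relationship of
branch-length estimates (long branches are noisier): squared residuals
from a first ordinary pass are pooled across loci, binned by fitted
value, smoothed by isotonic regression, and inverted into weights for a
second weighted pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import LocusBranchLengths, TreeModel


class RERError(ValueError):
    pass


@dataclass
class BranchLengthMatrix:
    """Loci x branches table of per-locus branch lengths (NaN = missing)."""

    table: pd.DataFrame  # index: locus ids, columns: branch ids
    branch_meta: pd.DataFrame  # index: branch ids; is_tip, tip_class, is_foreground

    @property
    def loci(self):
        return list(self.table.index)

    @property
    def branches(self):
        return list(self.table.columns)


@dataclass
class RERMatrix:
    """Loci x branches table of relative evolutionary rates."""

    table: pd.DataFrame
    branch_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def foreground_series(self) -> pd.Series:
        fg = self.branch_meta.index[self.branch_meta.is_foreground]
        if len(fg) != 1:
            raise RERError("no unique foreground branch in metadata")
        return self.table[fg[0]]


def build_branch_matrix(
    locus_lengths: list[LocusBranchLengths], master: TreeModel
) -> BranchLengthMatrix:
    """Stack per-locus estimates into a loci x branches matrix.

    Branch order follows the master tree's postorder; branches a locus
    could not resolve stay missing.
    """
    branch_ids = master.branch_ids()
    known = set(branch_ids)
    rows = {}
    for ll in locus_lengths:
        extra = set(ll.lengths) - known
        if extra:
            raise RERError(
                f"locus {ll.locus_id!r} has unknown branches: {sorted(extra)}"
            )
        rows[ll.locus_id] = [ll.lengths.get(b, np.nan) for b in branch_ids]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=branch_ids)
    table = table.loc[[ll.locus_id for ll in locus_lengths]]
    tips = set(master.tip_labels())
    meta = pd.DataFrame(
        {
            "is_tip": [b in tips for b in branch_ids],
            "tip_class": [master.tip_classes.get(b, "other") for b in branch_ids],
            "is_foreground": [b == master.foreground_branch for b in branch_ids],
        },
        index=branch_ids,
    )
    return BranchLengthMatrix(table, meta)


def _transform(x: np.ndarray, name: str) -> np.ndarray:
    if name == "sqrt":
        return np.sqrt(x)
    if name == "none":
        return x
    raise RERError(f"unknown transform {name!r}")


def compute_rer(
    matrix: BranchLengthMatrix,
    transform: str = "sqrt",
    weighted: bool = True,
    scale: bool = True,
    cutoff: float = 0.0,
    min_branches: int = 4,
    min_loci: int = 10,
    n_bins: int = 10,
) -> RERMatrix:
    """Relative evolutionary rates from a branch-length matrix.

    Pipeline: (1) lengths strictly below ``cutoff`` are set missing
    (``cutoff=0`` therefore keeps zero-length branches); (2) with
    ``scale`` each locus row is divided by its row sum over observed
    branches; (3) the master expectation per branch is the across-locus
    mean of the scaled lengths; (4) ``transform`` is applied to both;
    (5) per locus, transformed lengths are regressed (with intercept) on
    the transformed expectation, using inverse-variance weights from an
    isotonic variance-mean fit when ``weighted``; the standardised
    residuals are the RERs. Loci with fewer than ``min_branches``
    observed branches get all-missing rows.
    """
    df = matrix.table
    if len(df) < min_loci:
        raise RERError(f"need at least {min_loci} loci, got {len(df)}")
    X = df.to_numpy(dtype=float).copy()
    X[X < cutoff] = np.nan

    obs_per_locus = np.sum(~np.isnan(X), axis=1)
    usable = obs_per_locus >= min_branches
    if usable.sum() < min_loci:
        raise RERError(
            f"only {int(usable.sum())} loci have >= {min_branches} observed branches"
        )

    if scale:
        rowsum = np.nansum(X, axis=1, keepdims=True)
        rowsum[rowsum == 0] = np.nan
        S = X / rowsum
    else:
        S = X

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        expect = np.nanmean(np.where(usable[:, None], S, np.nan), axis=0)
    dead = ~np.isfinite(expect)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} branches have no usable observations; "
            "their RERs are set missing"
        )

    T = _transform(S, transform)
    te = _transform(np.where(dead, np.nan, expect), transform)

    n_loci, n_branch = T.shape
    resid = np.full_like(T, np.nan)
    fitted = np.full_like(T, np.nan)

    def regress(w=None):
        for i in range(n_loci):
            if not usable[i]:
                continue
            m = np.isfinite(T[i]) & np.isfinite(te)
            if w is not None:
                m &= np.isfinite(w[i])
            if m.sum() < min_branches:
                continue
            x, y = te[m], T[i][m]
            ww = w[i][m] if w is not None else np.ones(m.sum())
            W = ww.sum()
            xbar = (ww * x).sum() / W
            ybar = (ww * y).sum() / W
            sxx = (ww * (x - xbar) ** 2).sum()
            if sxx <= 0:
                slope = 0.0
            else:
                slope = (ww * (x - xbar) * (y - ybar)).sum() / sxx
            inter = ybar - slope * xbar
            f = slope * x + inter
            fitted[i, m] = f
            resid[i, m] = y - f

    regress()

    weights = None
    if weighted:
        m = np.isfinite(resid)
        f_all = fitted[m]
        r2_all = resid[m] ** 2
        if f_all.size >= n_bins:
            # quantile bins of fitted values -> isotonic variance fit
            qs = np.quantile(f_all, np.linspace(0, 1, n_bins + 1))
            bin_idx = np.clip(np.searchsorted(qs, f_all, side="right") - 1, 0, n_bins - 1)
            bf, bv = [], []
            for b in range(n_bins):
                sel = bin_idx == b
                if sel.sum() >= 3:
                    bf.append(f_all[sel].mean())
                    bv.append(r2_all[sel].mean())
            if len(bf) >= 2:
                from sklearn.isotonic import IsotonicRegression

                iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
                iso.fit(bf, bv)
                vhat = np.full(fitted.shape, np.nan)
                fin = np.isfinite(fitted)
                vhat[fin] = iso.predict(fitted[fin])
                floor = max(1e-12, np.nanmean(vhat) * 1e-3)
                weights = 1.0 / np.maximum(vhat, floor)
        if weights is not None:
            resid[:] = np.nan
            fitted[:] = np.nan
            regress(weights)

    # standardise per locus: sqrt(w)*r has ~constant variance
    rer = np.full_like(resid, np.nan)
    for i in range(n_loci):
        m = np.isfinite(resid[i])
        if not m.any():
            continue
        ww = weights[i][m] if weights is not None else np.ones(m.sum())
        z = np.sqrt(ww) * resid[i][m]
        dof = max(m.sum() - 2, 1)
        sd = np.sqrt((z**2).sum() / dof)
        # residuals at floating-point noise level mean an exactly
        # proportional locus tree: RER is 0, not noise blown up by 1/sd
        scale_y = max(np.abs(T[i][m]).max(), 1e-30)
        if np.abs(resid[i][m]).max() < 1e-9 * scale_y or sd == 0:
            rer[i, m] = 0.0
        else:
            rer[i, m] = z / sd
    rer[:, dead] = np.nan

    out = pd.DataFrame(rer, index=df.index, columns=df.columns)
    return RERMatrix(
        out,
        matrix.branch_meta,
        provenance={
            "transform": transform,
            "weighted": weighted,
            "scale": scale,
            "cutoff": cutoff,
        },
    )
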