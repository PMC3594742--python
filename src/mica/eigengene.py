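"""Module eigengenes via (weighted) principal component analysis.

An eigengene is the unit-norm first principal component of a module's
standardized expression profiles, the module's summary profile across
samples. The weighted variant uses fuzzy memberships as gene weights in
the covariance computation,

    C = X^T W X / sum(w),   W = diag(w),

which reduces exactly to the unweighted eigengene at uniform weights.
The sign is oriented so the eigengene correlates nonnegatively with the
weighted mean expression of its module, making outputs deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import Eigengene, ExpressionMatrix, MembershipMatrix

#: MM cutoffs of the stability scan: 5% steps from 10% to 90%
DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.10, 0.9001, 0.05), 2))


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize gene profiles; returns (standardized, constant mask)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    return (values - mu) / sd, constant


def weighted_eigengene(
    expr: ExpressionMatrix, weights, module_id=None
) -> Eigengene:
    """First principal component with per-gene nonnegative weights."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (expr.n_genes,):
        raise ValueError("one weight per gene required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.all(w == 0):
        raise ValueError("weights must not all be zero")
    x, constant = _standardize(expr.values)
    if np.any(constant & (w > 0)):
        warnings.warn("constant genes forced to zero weight", stacklevel=2)
        w = np.where(constant, 0.0, w)
        if np.all(w == 0):
            raise ValueError("all positively weighted genes are constant")
    cov = (x.T * w) @ x / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    var_explained = float(evals[-1] / evals.sum()) if evals.sum() > 0 else 0.0
    mean_profile = (w @ x) / w.sum()
    if float(v @ mean_profile) < 0:
        v = -v
    v = v / np.linalg.norm(v)
    return Eigengene(
        module_id, list(expr.sample_ids), v, var_explained,
        n_genes=int((w > 0).sum()),
    )


def eigengene_at_cutoff(
    expr: ExpressionMatrix,
    mm: MembershipMatrix,
    module_id: int,
    cutoff: float,
) -> Eigengene:
    """Unweighted eigengene of the genes passing an MM cutoff.

    Fewer than 2 passing genes yields an undefined eigengene carrying
    the passing count.
    """
    col = mm.mm[:, module_id - 1]
    passing = [g for g, v in zip(mm.gene_ids, col) if v >= cutoff]
    passing = [g for g in passing if g in set(expr.gene_ids)]
    if len(passing) < 2:
        return Eigengene(
            module_id, list(expr.sample_ids), np.array([]), 0.0,
            n_genes=len(passing), is_defined=False,
        )
    sub = expr.subset_genes(passing)
    return weighted_eigengene(sub, np.ones(sub.n_genes), module_id)


@dataclass
class StabilityProfile:
    """Mean eigengene agreement between MM cutoffs and vs the weighted PCA."""

    cutoffs: list[float]
    pairwise_corr: np.ndarray  # |cor| averaged over modules
    corr_to_weighted: np.ndarray
    n_undefined: int = 0

    def mean_correlation(self, cutoff_index: int) -> float:
        """Mean agreement of one cutoff with all others and the weighted PCA."""
        row = np.delete(self.pairwise_corr[cutoff_index], cutoff_index)
        parts = np.concatenate([row, [self.corr_to_weighted[cutoff_index]]])
        parts = parts[~np.isnan(parts)]
        return float(parts.mean()) if parts.size else np.nan


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(abs(np.corrcoef(a, b)[0, 1]))


def stability_profile(
    expr: ExpressionMatrix,
    mm: MembershipMatrix,
    cutoffs=DEFAULT_CUTOFFS,
) -> StabilityProfile:
    """Eigengene stability across MM cutoffs.

    For every module and cutoff the unweighted cutoff eigengene is
    computed; entries average |cor| over modules, skipping undefined
    eigengenes (count reported on the profile).
    """
    cutoffs = [float(c) for c in cutoffs]
    n_cut = len(cutoffs)
    modules = range(1, mm.n_modules + 1)
    egs = {}
    n_undefined = 0
    for k in modules:
        w_eg = weighted_eigengene(expr, mm.mm[:, k - 1], k) if np.any(
            mm.mm[:, k - 1] > 0
        ) else None
        egs[(k, "weighted")] = w_eg
        for ci, cut in enumerate(cutoffs):
            eg = eigengene_at_cutoff(expr, mm, k, cut)
            if not eg.is_defined:
                n_undefined += 1
                eg = None
            egs[(k, ci)] = eg

    pairwise = np.full((n_cut, n_cut), np.nan)
    to_weighted = np.full(n_cut, np.nan)
    for a in range(n_cut):
        vals = [
            _abs_corr(egs[(k, a)].values, egs[(k, "weighted")].values)
            for k in modules
            if egs[(k, a)] is not None and egs[(k, "weighted")] is not None
        ]
        vals = [v for v in vals if not np.isnan(v)]
        if vals:
            to_weighted[a] = np.mean(vals)
        for b in range(a, n_cut):
            vals = [
                _abs_corr(egs[(k, a)].values, egs[(k, b)].values)
                for k in modules
                if egs[(k, a)] is not None and egs[(k, b)] is not None
            ]
            vals = [v for v in vals if not np.isnan(v)]
            if vals:
                pairwise[a, b] = pairwise[b, a] = np.mean(vals)
    return StabilityProfile(cutoffs, pairwise, to_weighted, n_undefined)
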