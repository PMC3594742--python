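"""Scale-free-topology fitting and network thresholding.

The connectivity of gene i at power p is k_i = sum_{j != i} a_ij**p.
The scale-free fit bins k into equal-width bins and regresses
log10(bin frequency) on log10(mean bin connectivity); the signed R2 is
-sign(slope) * R2, so a decreasing, power-law-like degree distribution
scores positively.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datatypes import AssociationMatrix, EdgeList, SFTFit

DEFAULT_POWERS = list(range(1, 21))
DEFAULT_N_BINS = 10
R2_RECOMMENDED = 0.9


def signed_r2(connectivities: np.ndarray, n_bins: int = DEFAULT_N_BINS):
    """Signed R2 of the log-log binned connectivity distribution.

    Returns (r2_signed, slope). Degenerate inputs (all-equal k, or fewer
    than two usable bins) yield (0.0, 0.0) with a warning.
    """
    k = np.asarray(connectivities, dtype=float)
    if k.size == 0 or np.all(k == k[0]):
        warnings.warn("degenerate connectivity distribution; R2 set to 0", stacklevel=2)
        return 0.0, 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    mids = []
    freqs = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        in_bin = (k >= edges[b]) & ((k < edges[b + 1]) | (b == n_bins - 1))
        mean_k = k[in_bin].mean()
        if mean_k <= 0:
            continue
        mids.append(mean_k)
        freqs.append(counts[b])
    if len(mids) < 2:
        warnings.warn("fewer than two usable bins; R2 set to 0", stacklevel=2)
        return 0.0, 0.0
    lx = np.log10(np.asarray(mids))
    ly = np.log10(np.asarray(freqs, dtype=float))
    if np.all(lx == lx[0]):
        warnings.warn("constant binned connectivity; R2 set to 0", stacklevel=2)
        return 0.0, 0.0
    fit = stats.linregress(lx, ly)
    r2 = float(fit.rvalue**2)
    return float(-np.sign(fit.slope) * r2), float(fit.slope)


def connectivity(assoc: AssociationMatrix, power: int = 1) -> np.ndarray:
    """Soft connectivity k_i = sum_{j != i} a_ij**power."""
    a = np.power(assoc.scores, power)
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def sft_fit(
    assoc: AssociationMatrix,
    powers: list[int] | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> SFTFit:
    """Scale-free fit of the association matrix across soft powers."""
    if n_bins < 5:
        raise ValueError("need at least 5 bins")
    powers = list(powers) if powers is not None else list(DEFAULT_POWERS)
    r2s, slopes = [], []
    for p in powers:
        r2, slope = signed_r2(connectivity(assoc, p), n_bins)
        r2s.append(r2)
        slopes.append(slope)
    return SFTFit(powers, r2s, slopes, n_bins)


def pick_soft_power(fit: SFTFit, r2_min: float = R2_RECOMMENDED) -> int | None:
    """Smallest power whose signed R2 passes the threshold (None if none)."""
    for p, r2 in zip(fit.powers, fit.r2_signed):
        if r2 >= r2_min:
            return p
    return None


def pick_hard_threshold(
    assoc: AssociationMatrix,
    step: float = 0.05,
    r2_min: float = R2_RECOMMENDED,
    n_bins: int = DEFAULT_N_BINS,
) -> float | None:
    """Lowest binarization cutoff whose degree distribution passes R2.

    Scans step, 2*step, ...; cutoffs that leave no edges are skipped.
    Returns None when no scanned cutoff passes.
    """
    if not (0 < step < 1):
        raise ValueError("step must lie in (0, 1)")
    a = assoc.scores.copy()
    np.fill_diagonal(a, -np.inf)
    max_score = a.max()
    cutoff = step
    while cutoff <= max_score + 1e-12:
        deg = (a >= cutoff).sum(axis=1).astype(float)
        if deg.sum() > 0 and not np.all(deg == deg[0]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2, _ = signed_r2(deg, n_bins)
            if r2 >= r2_min:
                return round(cutoff / step) * step
        cutoff += step
    return None


def binarize(assoc: AssociationMatrix, cutoff: float) -> EdgeList:
    """Hard-threshold an association matrix into an edge list.

    Edge iff score >= cutoff (i != j); isolated nodes stay in the node
    list so unplaced-gene accounting remains possible downstream.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    ids = assoc.gene_ids
    iu, ju = np.triu_indices(assoc.n_genes, k=1)
    hit = assoc.scores[iu, ju] >= cutoff
    edges = {frozenset((ids[i], ids[j])) for i, j in zip(iu[hit], ju[hit])}
    return EdgeList(list(ids), edges, cutoff_used=float(cutoff))
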