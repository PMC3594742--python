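"""End-to-end MICA convenience driver.

Chains the pipeline stages: MIC association matrix, hard thresholding
into an unweighted network, ICMg fuzzy module detection, and hardened /
cutoff-thresholded partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    AssociationMatrix,
    EdgeList,
    ExpressionMatrix,
    MembershipMatrix,
    ModulePartition,
)
from .icmg import SamplerConfig, harden, run_icmg
from .mic import mic_matrix
from .topology import binarize, pick_hard_threshold, signed_r2


@dataclass
class MICAResult:
    assoc: AssociationMatrix
    edges: EdgeList
    mm: MembershipMatrix
    partition: ModulePartition
    cutoff: float


def run_mica(
    expr: ExpressionMatrix,
    n_modules: int,
    cutoff: float | str = "auto",
    exponent: float = 0.6,
    alpha: float = 10.0,
    beta: float = 0.1,
    burn_in: int = 2000,
    thin: int = 10,
    sampling_iters: int = 1000,
    seed: int = 0,
    assoc: AssociationMatrix | None = None,
) -> MICAResult:
    """MIC matrix -> hard threshold -> ICMg -> hardened partition.

    ``cutoff="auto"`` uses the lowest 0.05-step cutoff whose degree
    distribution passes the scale-free R2 criterion, falling back to the
    best-fitting scanned cutoff when none passes. The default sampler
    schedule is the reduced desk-scale one; pass the full schedule
    explicitly for production-size runs.
    """
    if assoc is None:
        assoc = mic_matrix(expr, exponent=exponent)
    if cutoff == "auto":
        chosen = pick_hard_threshold(assoc)
        if chosen is None:
            chosen = _best_fit_cutoff(assoc)
            warnings.warn(
                f"no cutoff passes the scale-free criterion; using best "
                f"fit at {chosen:.2f}",
                stacklevel=2,
            )
    else:
        chosen = float(cutoff)
    edges = binarize(assoc, chosen)
    config = SamplerConfig(
        n_components=n_modules,
        alpha=alpha,
        beta=beta,
        burn_in=burn_in,
        thin=thin,
        sampling_iters=sampling_iters,
        seed=seed,
    )
    mm = run_icmg(edges, config)
    return MICAResult(assoc, edges, mm, harden(mm), chosen)


def _best_fit_cutoff(assoc: AssociationMatrix, step: float = 0.05) -> float:
    """Scanned cutoff with the highest signed R2 (fallback rule)."""
    a = assoc.scores.copy()
    np.fill_diagonal(a, -np.inf)
    best, best_r2 = step, -np.inf
    cutoff = step
    while cutoff <= a.max() + 1e-12:
        deg = (a >= cutoff).sum(axis=1).astype(float)
        if deg.sum() > 0 and not np.all(deg == deg[0]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2, _ = signed_r2(deg)
            if r2 > best_r2:
                best, best_r2 = cutoff, r2
        cutoff += step
    return round(best / step) * step
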