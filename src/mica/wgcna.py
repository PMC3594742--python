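"""Simplified correlation-network baseline (WGCNA-style).

Pipeline: |Pearson r| -> soft-threshold power chosen by scale-free fit
-> power adjacency -> topological overlap matrix (TOM) -> average-linkage
hierarchical clustering of 1 - TOM cut to a requested module count ->
eigengene-correlation module merging. The dynamic tree cut of the full
method is replaced by a static cut plus a minimum-size rule; the
baseline's role here is comparative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import AssociationMatrix, ExpressionMatrix, ModulePartition
from .eigengene import weighted_eigengene
from .mic import pearson_matrix
from .topology import R2_RECOMMENDED, pick_soft_power, sft_fit

DEFAULT_MIN_SIZE = 20
DEFAULT_MERGE_R = 0.8


@dataclass
class TOMMatrix:
    """Topological overlap of a weighted adjacency; dist = 1 - tom."""

    gene_ids: list[str]
    tom: np.ndarray

    @property
    def dist(self) -> np.ndarray:
        return 1.0 - self.tom


def tom(adj: AssociationMatrix) -> TOMMatrix:
    """Topological overlap measure.

    TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij) with
    the u-sum excluding both endpoints and k the adjacency-weighted
    degree; the diagonal is 1 by convention.
    """
    a = adj.scores.copy()
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # u-sum; zero diagonal removes u in {i, j}
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    t = num / den
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2, 0.0, 1.0)
    return TOMMatrix(list(adj.gene_ids), t)


def cluster_to_modules(
    tomm: TOMMatrix, n_modules: int, min_size: int = DEFAULT_MIN_SIZE
) -> ModulePartition:
    """Average-linkage clustering of DistTOM cut to ``n_modules`` groups.

    Groups smaller than ``min_size`` are dissolved into the unplaced
    bucket; surviving module labels are renumbered contiguously in
    order of first appearance.
    """
    n = len(tomm.gene_ids)
    if n_modules < 2:
        raise ValueError("need at least 2 modules")
    if n_modules > n:
        raise ValueError("more modules than genes")
    d = squareform(tomm.dist, checks=False)
    tree = linkage(d, method="average")
    raw = fcluster(tree, t=n_modules, criterion="maxclust")
    sizes = np.bincount(raw)
    relabel = {}
    assignments = []
    for lab in raw:
        if sizes[lab] < min_size:
            assignments.append(frozenset())
        else:
            if lab not in relabel:
                relabel[lab] = len(relabel) + 1
            assignments.append(frozenset({relabel[lab]}))
    return ModulePartition(list(tomm.gene_ids), assignments, max(len(relabel), 1))


def _module_eigengenes(part: ModulePartition, expr: ExpressionMatrix) -> dict:
    egs = {}
    for k in range(1, part.n_modules + 1):
        genes = part.module_genes(k)
        if len(genes) < 1:
            continue
        sub = expr.subset_genes(genes)
        if sub.n_genes == 1:
            x = sub.values[0]
            sd = x.std()
            v = (x - x.mean()) / (sd if sd else 1.0)
            nrm = np.linalg.norm(v)
            egs[k] = v / nrm if nrm else None
        else:
            egs[k] = weighted_eigengene(sub, np.ones(sub.n_genes), k).values
    return egs


def merge_close_modules(
    part: ModulePartition,
    expr: ExpressionMatrix,
    r_min: float = DEFAULT_MERGE_R,
) -> ModulePartition:
    """Iteratively merge the module pair with the highest eigengene
    correlation above ``r_min``, recomputing eigengenes after each merge."""
    current = part
    while current.n_modules >= 2:
        egs = _module_eigengenes(current, expr)
        labels = sorted(k for k, v in egs.items() if v is not None)
        best = None
        for ai in range(len(labels)):
            for bi in range(ai + 1, len(labels)):
                a, b = labels[ai], labels[bi]
                r = float(np.corrcoef(egs[a], egs[b])[0, 1])
                if r > r_min and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        relabel = {}
        new_assignments = []
        for ass in current.assignments:
            if not ass:
                new_assignments.append(frozenset())
                continue
            mapped = {a if m == b else m for m in ass}
            new_assignments.append(frozenset(mapped))
        seen = {}
        final = []
        for ass in new_assignments:
            out = set()
            for m in sorted(ass):
                if m not in seen:
                    seen[m] = len(seen) + 1
                out.add(seen[m])
            final.append(frozenset(out))
        current = ModulePartition(
            list(current.gene_ids), final, max(len(seen), 1)
        )
    return current


def run_baseline(
    expr: ExpressionMatrix,
    r2_min: float = R2_RECOMMENDED,
    n_modules: int | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    merge_r: float = DEFAULT_MERGE_R,
) -> tuple[ModulePartition, int]:
    """Full baseline pipeline; returns (partition, chosen soft power).

    When no power passes ``r2_min`` the best-fitting power is used with a
    warning. ``n_modules=None`` picks the cut (2..15) maximizing the
    mean silhouette on the TOM dissimilarity.
    """
    assoc = pearson_matrix(expr, absolute=True)
    fit = sft_fit(assoc)
    power = pick_soft_power(fit, r2_min)
    if power is None:
        power = fit.powers[int(np.argmax(fit.r2_signed))]
        warnings.warn(
            f"no power passes R2 >= {r2_min}; using best fit at power "
            f"{power}",
            stacklevel=2,
        )
    adj = AssociationMatrix(
        list(assoc.gene_ids), np.power(assoc.scores, power), "pearson_power"
    )
    tomm = tom(adj)
    if n_modules is None:
        n_modules = _auto_module_count(tomm)
    part = cluster_to_modules(tomm, n_modules, min_size)
    part = merge_close_modules(part, expr, merge_r)
    return part, int(power)


def _auto_module_count(tomm: TOMMatrix, k_max: int | None = None) -> int:
    """Cut height chosen by mean silhouette on the TOM dissimilarity.

    The candidate range extends to about a quarter of the gene count so
    background genes can fall out as dissolvable singleton leaves (the
    job dynamic tree cut does in the full method).
    """
    from sklearn.metrics import silhouette_score

    n = len(tomm.gene_ids)
    if k_max is None:
        k_max = max(15, min(n // 4, 60))
    d = squareform(tomm.dist, checks=False)
    tree = linkage(d, method="average")
    best_k, best_s = 2, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(tomm.dist, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k
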