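"""Maximal information coefficient (MIC) estimation.

MIC searches axis-aligned grids over the ranks of a variable pair and
reports the maximum grid mutual information, normalized by
log2(min(x_bins, y_bins)). The search space is limited to grids with
x_bins * y_bins < n**exponent (default exponent 0.6); the minimal 2x2
grid is always searched so small samples remain scoreable.

Two search modes are provided. ``exhaustive`` enumerates every cut
placement (feasible for small n) and serves as the oracle. ``heuristic``
follows the MINE scheme: partition one axis, then run an exact dynamic
program over cut placements on the other axis, in both orientations.
When the fixed axis has only two bins and few candidate boundaries, the
single fixed cut is itself enumerated, which makes the heuristic exact
for every grid that a small sample admits.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from numba import njit

from .datatypes import AssociationMatrix, ExpressionMatrix, GridPartition, MICResult

DEFAULT_EXPONENT = 0.6
#: MINE-style clump factor: cap on DP cut candidates per optimized bin.
DEFAULT_CLUMP_FACTOR = 15
#: fixed-axis 2-bin cuts are enumerated exhaustively up to this many candidates
_ENUMERATE_LIMIT = 64


# ---------------------------------------------------------------------------
# shared helpers


def _boundaries(sorted_vals: np.ndarray) -> np.ndarray:
    """Positions p where a cut may fall between sorted_vals[p-1] and [p].

    Cuts are only allowed between distinct values, so tied points are
    never split across a grid line.
    """
    return np.flatnonzero(sorted_vals[1:] != sorted_vals[:-1]) + 1


def _mi_bits(counts: np.ndarray) -> float:
    """Mutual information of a contingency table, in bits."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _grid_sizes(n: int, exponent: float):
    """All (x_bins, y_bins) pairs admitted for a sample of size n."""
    bound = float(n) ** exponent
    out = [(2, 2)]  # always admitted
    a = 2
    while True:
        if a * 2 >= bound and a > 2:
            break
        b = 2
        while a * b < bound:
            if (a, b) != (2, 2):
                out.append((a, b))
            b += 1
        a += 1
    return out, bound


# ---------------------------------------------------------------------------
# exhaustive search


def _exhaustive(x: np.ndarray, y: np.ndarray, exponent: float):
    n = x.size
    order_x = np.argsort(x, kind="stable")
    order_y = np.argsort(y, kind="stable")
    cand_x = _boundaries(x[order_x])
    cand_y = _boundaries(y[order_y])
    if cand_x.size == 0 or cand_y.size == 0:
        return 0.0, None
    # rank position of each point along each axis
    pos_x = np.empty(n, dtype=np.int64)
    pos_x[order_x] = np.arange(n)
    pos_y = np.empty(n, dtype=np.int64)
    pos_y[order_y] = np.arange(n)

    sizes, _ = _grid_sizes(n, exponent)
    best = (0.0, None)
    for a, b in sizes:
        if a - 1 > cand_x.size or b - 1 > cand_y.size:
            continue
        norm = np.log2(min(a, b))
        for xc in combinations(cand_x.tolist(), a - 1):
            bx = np.searchsorted(np.asarray(xc), pos_x, side="right")
            for yc in combinations(cand_y.tolist(), b - 1):
                by = np.searchsorted(np.asarray(yc), pos_y, side="right")
                counts = np.zeros((a, b))
                np.add.at(counts, (bx, by), 1)
                val = _mi_bits(counts) / norm
                if val > best[0] + 1e-15:
                    best = (val, GridPartition(a, b, tuple(xc), tuple(yc)))
    return best


# ---------------------------------------------------------------------------
# heuristic search (MINE-style DP)


@njit(cache=True)
def _dp_best_f(pref: np.ndarray, n: float, l_max: int) -> np.ndarray:
    """Max over l-bin partitions of sum_cols sum_rows (c/n)*log2(c/n_col).

    ``pref`` is the (n_seg+1, q) cumulative row-count table over DP
    segments. Returns the optimum for each l = 1..l_max; adding the fixed
    axis entropy H(Q) yields the grid mutual information.
    """
    n_seg = pref.shape[0] - 1
    q = pref.shape[1]
    G = np.full((n_seg + 1, n_seg + 1), -np.inf)
    for s in range(n_seg):
        for t in range(s + 1, n_seg + 1):
            ncol = 0.0
            for b in range(q):
                ncol += pref[t, b] - pref[s, b]
            acc = 0.0
            if ncol > 0:
                for b in range(q):
                    c = pref[t, b] - pref[s, b]
                    if c > 0:
                        acc += c * np.log2(c / ncol)
            G[s, t] = acc / n
    F = np.full((n_seg + 1, l_max + 1), -np.inf)
    for t in range(1, n_seg + 1):
        F[t, 1] = G[0, t]
    for l in range(2, l_max + 1):
        for t in range(l, n_seg + 1):
            best = -np.inf
            for s in range(l - 1, t):
                v = F[s, l - 1] + G[s, t]
                if v > best:
                    best = v
            F[t, l] = best
    return F[n_seg, 1 : l_max + 1]


def _equipartition(cand: np.ndarray, n: int, q: int) -> np.ndarray:
    """Choose up to q-1 cut positions from ``cand`` near the q-quantiles."""
    chosen = []
    prev = 0
    for i in range(1, q):
        target = i * n / q
        avail = cand[cand > prev]
        if avail.size == 0:
            break
        pick = avail[np.argmin(np.abs(avail - target))]
        chosen.append(int(pick))
        prev = pick
    return np.array(chosen, dtype=np.int64)


def _fixed_partitions(cand: np.ndarray, n: int, q: int):
    """Candidate fixed-axis partitions (each a cut-position array)."""
    parts = []
    if q == 2 and cand.size <= _ENUMERATE_LIMIT:
        for p in cand:
            parts.append(np.array([p], dtype=np.int64))
    else:
        eq = _equipartition(cand, n, q)
        if eq.size == q - 1:
            parts.append(eq)
    return parts


def _heuristic(
    x: np.ndarray,
    y: np.ndarray,
    exponent: float,
    clump_factor: int = DEFAULT_CLUMP_FACTOR,
):
    n = x.size
    _, bound = _grid_sizes(n, exponent)
    best_val = 0.0
    best_grid = None

    for fixed, free, swap in ((y, x, False), (x, y, True)):
        order_fixed = np.argsort(fixed, kind="stable")
        order_free = np.argsort(free, kind="stable")
        cand_fixed = _boundaries(fixed[order_fixed])
        cand_free = _boundaries(free[order_free])
        if cand_fixed.size == 0 or cand_free.size == 0:
            continue
        pos_fixed = np.empty(n, dtype=np.int64)
        pos_fixed[order_fixed] = np.arange(n)

        q = 2
        while q == 2 or q * 2 < bound:
            l_max = max(2, int(np.ceil(bound / q)) - 1)
            while l_max > 2 and l_max * q >= bound:
                l_max -= 1
            for cuts in _fixed_partitions(cand_fixed, n, q):
                q_eff = cuts.size + 1
                if q_eff < 2:
                    continue
                row_of = np.searchsorted(cuts, pos_fixed, side="right")
                # DP candidates: distinct-value boundaries on the free
                # axis, thinned to the clump-factor cap for large n
                cand = cand_free
                cap = max(clump_factor * l_max, 16)
                if cand.size > cap:
                    idx = np.unique(
                        np.round(np.linspace(0, cand.size - 1, cap)).astype(int)
                    )
                    cand = cand[idx]
                seg_edges = np.concatenate(([0], cand, [n]))
                n_seg = seg_edges.size - 1
                # per-segment row counts in free-axis order
                row_sorted = row_of[order_free]
                pref = np.zeros((n_seg + 1, q_eff))
                for s in range(n_seg):
                    seg = row_sorted[seg_edges[s] : seg_edges[s + 1]]
                    pref[s + 1] = pref[s] + np.bincount(seg, minlength=q_eff)
                h_fixed = 0.0
                tot = pref[-1]
                pz = tot[tot > 0] / n
                h_fixed = float(-(pz * np.log2(pz)).sum())
                f_vals = _dp_best_f(pref, float(n), l_max)
                for l in range(2, l_max + 1):
                    if l * q_eff >= bound and not (l == 2 and q_eff == 2):
                        continue
                    mi = f_vals[l - 1] + h_fixed
                    val = mi / np.log2(min(l, q_eff))
                    if val > best_val + 1e-15:
                        best_val = val
                        a, b = (l, q_eff) if not swap else (q_eff, l)
                        best_grid = GridPartition(a, b)
            q += 1
    return best_val, best_grid


# ---------------------------------------------------------------------------
# public API


def mic_score(
    x,
    y,
    exponent: float = DEFAULT_EXPONENT,
    mode: str = "heuristic",
    clump_factor: int = DEFAULT_CLUMP_FACTOR,
) -> MICResult:
    """Maximal information coefficient of a variable pair.

    Parameters
    ----------
    x, y
        Equal-length numeric vectors, n >= 4.
    exponent
        Grid resolution bound: searched grids satisfy
        x_bins * y_bins < n**exponent (2x2 always allowed).
    mode
        "heuristic" (MINE-style DP, default) or "exhaustive"
        (full enumeration; small n only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("MIC needs at least 4 observations")
    if not (0 < exponent <= 1):
        raise ValueError("exponent must lie in (0, 1]")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    if np.all(x == x[0]) or np.all(y == y[0]):
        return MICResult(0.0, None, n, exponent)

    if mode == "exhaustive":
        if n > 60:
            raise ValueError("exhaustive mode is only feasible for n <= 60")
        val, grid = _exhaustive(x, y, exponent)
    elif mode == "heuristic":
        val, grid = _heuristic(x, y, exponent, clump_factor)
    else:
        raise ValueError("mode must be 'heuristic' or 'exhaustive'")
    return MICResult(min(val, 1.0), grid, n, exponent)


def mic_matrix(
    expr: ExpressionMatrix,
    exponent: float = DEFAULT_EXPONENT,
    mode: str = "heuristic",
) -> AssociationMatrix:
    """All-pairs MIC over the genes of an expression matrix.

    Pair computations are independent; the result does not depend on gene
    ordering or evaluation order, and the diagonal is set to 1.
    """
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")
    g = expr.n_genes
    scores = np.eye(g)
    vals = expr.values
    for i in range(g):
        for j in range(i + 1, g):
            try:
                res = mic_score(vals[i], vals[j], exponent, mode)
            except ValueError as err:
                raise ValueError(
                    f"MIC failed for pair ({expr.gene_ids[i]}, "
                    f"{expr.gene_ids[j]}): {err}"
                ) from err
            scores[i, j] = scores[j, i] = res.mic
    return AssociationMatrix(list(expr.gene_ids), scores, "mic")


def pearson_matrix(expr: ExpressionMatrix, absolute: bool = True) -> AssociationMatrix:
    """All-pairs Pearson correlation (|r| when ``absolute``).

    Constant genes get correlation 0 against everything, with a warning.
    """
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    vals = expr.values
    sds = vals.std(axis=1)
    constant = sds == 0
    if np.any(constant):
        names = [g for g, c in zip(expr.gene_ids, constant) if c]
        warnings.warn(
            f"constant genes get zero correlations: {names}", stacklevel=2
        )
    safe = vals.copy()
    safe[constant] = np.random.default_rng(0).normal(size=(constant.sum(), vals.shape[1]))
    r = np.corrcoef(safe)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    if absolute:
        r = np.abs(r)
        tag = "pearson_abs"
    else:
        tag = "pearson"
    r = (r + r.T) / 2  # enforce exact symmetry against float noise
    return AssociationMatrix(list(expr.gene_ids), r, tag)
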