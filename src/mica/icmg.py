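"""Interaction component model for genes (ICMg).

A link-community latent-variable model: every network edge carries a
latent component label, components own node-affinity distributions with
a symmetric Dirichlet(beta) prior, and component proportions have a
Dirichlet(alpha) prior. A collapsed Gibbs sampler reassigns one link at
a time; after burn-in, component-node co-occurrence counts are
accumulated at a thinning interval and row-normalized into fuzzy module
memberships.

The conditional for link (i0, j0) given all other assignments is

    p(z0 = z) prop. (n'_z + alpha) / (N' + C*alpha)
              * (q'_{z,i0} + beta) * (q'_{z,j0} + beta)
              / ((2*n'_z + 1 + M*beta) * (2*n'_z + M*beta))

where primed counts exclude the interrogated link, C is the component
count and M the node count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import UNPLACED, EdgeList, MembershipMatrix, ModulePartition


@dataclass
class SamplerConfig:
    """ICMg run parameters.

    ``burn_in`` and ``sampling_iters`` count full sweeps over all links;
    memberships are accumulated every ``thin`` sweeps of the sampling
    phase. Defaults mirror a full-scale run; tests and desk-scale
    studies pass reduced schedules.
    """

    n_components: int = 12
    alpha: float = 10.0
    beta: float = 0.1
    burn_in: int = 40_000
    thin: int = 10
    sampling_iters: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("need at least 2 components")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.burn_in < 0 or self.sampling_iters < 0 or self.thin < 1:
            raise ValueError("invalid schedule")


@dataclass
class SamplerState:
    """Count statistics of a link-assignment configuration."""

    z: np.ndarray  # component per link
    n_z: np.ndarray  # links per component
    q: np.ndarray  # component x node endpoint co-occurrences
    n_links: int
    n_nodes: int

    def check_conservation(self) -> None:
        if int(self.n_z.sum()) != self.n_links:
            raise AssertionError("sum n_z != number of links")
        if not np.array_equal(self.q.sum(axis=1), 2 * self.n_z):
            raise AssertionError("sum_i q[z,i] != 2 n_z for some component")
        if np.any(self.n_z < 0) or np.any(self.q < 0):
            raise AssertionError("negative counts")


def state_from_labels(src: np.ndarray, dst: np.ndarray, z: np.ndarray,
                      n_components: int, n_nodes: int) -> SamplerState:
    """Build count statistics from explicit link labels."""
    n_z = np.bincount(z, minlength=n_components).astype(np.int64)
    q = np.zeros((n_components, n_nodes), dtype=np.int64)
    np.add.at(q, (z, src), 1)
    np.add.at(q, (z, dst), 1)
    return SamplerState(z.copy(), n_z, q, len(z), n_nodes)


def gibbs_conditional(
    state: SamplerState, link: tuple[int, int], config: SamplerConfig
) -> np.ndarray:
    """Normalized component probabilities for one link.

    ``state`` must already exclude the interrogated link from all counts
    (primed counts). ``link`` is an (i0, j0) node-index pair.
    """
    i0, j0 = link
    m = state.n_nodes
    if not (0 <= i0 < m and 0 <= j0 < m):
        raise ValueError(f"link endpoints ({i0}, {j0}) outside node set")
    c = config.n_components
    n_prime = state.n_links
    nz = state.n_z.astype(float)
    w = (nz + config.alpha) / (n_prime + c * config.alpha)
    w *= (state.q[:, i0] + config.beta) * (state.q[:, j0] + config.beta)
    w /= (2 * nz + 1 + m * config.beta) * (2 * nz + m * config.beta)
    return w / w.sum()


@njit(cache=True)
def _sweep(src, dst, z, n_z, q, alpha, beta, u):
    """One full Gibbs sweep over all links, in fixed input order."""
    n_links = src.size
    c = n_z.size
    m = q.shape[1]
    mb = m * beta
    for e in range(n_links):
        i0 = src[e]
        j0 = dst[e]
        old = z[e]
        n_z[old] -= 1
        q[old, i0] -= 1
        q[old, j0] -= 1
        total = 0.0
        # cumulative unnormalized weights (the N'+C*alpha term is
        # constant across components and cancels)
        cw = np.empty(c)
        for k in range(c):
            nk = n_z[k]
            w = (
                (nk + alpha)
                * (q[k, i0] + beta)
                * (q[k, j0] + beta)
                / ((2.0 * nk + 1.0 + mb) * (2.0 * nk + mb))
            )
            total += w
            cw[k] = total
        r = u[e] * total
        new = 0
        while cw[new] < r and new < c - 1:
            new += 1
        z[e] = new
        n_z[new] += 1
        q[new, i0] += 1
        q[new, j0] += 1


def run_icmg(
    edges: EdgeList,
    config: SamplerConfig,
    check_invariants: bool = False,
) -> MembershipMatrix:
    """Run the collapsed Gibbs sampler and return fuzzy memberships.

    Link labels are initialized by a single global Dirichlet(alpha) draw
    of component probabilities followed by a multinomial assignment per
    link. Deterministic given ``config.seed``; zero-degree nodes get
    uniform rows flagged unsupported.
    """
    if edges.n_edges == 0:
        raise ValueError("edge list is empty")
    c = config.n_components
    if c > edges.n_edges:
        warnings.warn(
            f"{c} components but only {edges.n_edges} links; "
            "some components may starve",
            stacklevel=2,
        )
    src, dst = edges.to_index_arrays()
    m = len(edges.nodes)
    rng = np.random.default_rng(config.seed)

    theta = rng.dirichlet(np.full(c, config.alpha))
    z = rng.choice(c, size=edges.n_edges, p=theta).astype(np.int64)
    state = state_from_labels(src, dst, z, c, m)

    for _ in range(config.burn_in):
        _sweep(src, dst, state.z, state.n_z, state.q,
               config.alpha, config.beta, rng.random(edges.n_edges))
        if check_invariants:
            state.check_conservation()

    acc = np.zeros((c, m), dtype=np.int64)
    n_samples = 0
    for it in range(config.sampling_iters):
        _sweep(src, dst, state.z, state.n_z, state.q,
               config.alpha, config.beta, rng.random(edges.n_edges))
        if check_invariants:
            state.check_conservation()
        if (it + 1) % config.thin == 0:
            acc += state.q
            n_samples += 1
    if n_samples == 0:  # degenerate schedule: fall back to final state
        acc = state.q.copy()
        n_samples = 1

    totals = acc.sum(axis=0).astype(float)
    supported = totals > 0
    mm = np.full((m, c), 1.0 / c)
    mm[supported] = (acc[:, supported].T / totals[supported, None])
    if np.any(~supported):
        warnings.warn(
            f"{int((~supported).sum())} zero-degree nodes get uniform "
            "memberships",
            stacklevel=2,
        )
    return MembershipMatrix(list(edges.nodes), mm, supported, n_samples)


def harden(mm: MembershipMatrix) -> ModulePartition:
    """Force each gene into its argmax-membership module.

    Ties break toward the lowest module index; unsupported genes are
    left unplaced.
    """
    assignments = []
    for row, sup in zip(mm.mm, mm.supported):
        if not sup:
            assignments.append(frozenset())
        else:
            assignments.append(frozenset({int(np.argmax(row)) + 1}))
    return ModulePartition(list(mm.gene_ids), assignments, mm.n_modules)


def threshold_membership(mm: MembershipMatrix, cutoff: float) -> ModulePartition:
    """Binary multi-assignment: a gene joins every module with mm >= cutoff."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    assignments = []
    for row, sup in zip(mm.mm, mm.supported):
        if not sup:
            assignments.append(frozenset())
        else:
            assignments.append(
                frozenset(int(k) + 1 for k in np.flatnonzero(row >= cutoff))
            )
    return ModulePartition(list(mm.gene_ids), assignments, mm.n_modules)
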