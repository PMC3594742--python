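"""Synthetic fixtures with the structure the pipeline assumes.

The expression generator plants latent-factor modules whose genes
follow the relationship archetypes seen in strain-panel data: linear,
high-threshold, logarithmic, quadratic, and two-condition
gene-by-environment (GxE) mixtures where the gene-gene relationship
differs between treated and control samples. Overlap genes load on two
factors, background genes are independent noise, and every generator is
a pure function of its design plus seed.

The GxE module mixes two response types: "shifted" genes track the
factor with a large mean offset under treatment, "flipping" genes track
the factor with the opposite slope under treatment. A shifted-flipping
pair is then a piecewise-linear function with near-zero pooled
correlation but near-perfect MIC, the Figure-1-style "complex"
relationship; the ground truth labels exactly those cross pairs "gxe".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import EdgeList, ExpressionMatrix
from .evaluation import AnnotationSet, propagate_annotations

#: treatment offset of shifted GxE genes, in factor standard deviations;
#: large enough that the two condition branches do not overlap
GXE_SHIFT = 6.0


@dataclass
class ModuleSpec:
    size: int
    loading: float = 1.0
    kind: str = "linear"  # linear | threshold | logarithmic | quadratic | gxe
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.kind not in {"linear", "threshold", "logarithmic", "quadratic", "gxe"}:
            raise ValueError(f"unknown relationship kind {self.kind!r}")


@dataclass
class SimulationDesign:
    n_samples: int = 100
    modules: list = field(default_factory=list)
    n_overlap_genes: int = 0
    n_background_genes: int = 0
    condition_split: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.condition_split < 1):
            raise ValueError("condition_split must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted structure sufficient to score recovery."""

    module_of: dict  # gene -> frozenset of module labels (1-based)
    pair_types: dict  # frozenset({g1, g2}) -> relationship label
    conditions: np.ndarray  # 0 = control, 1 = treated, per sample
    factors: np.ndarray  # module x sample latent factors

    def labels(self, gene_ids) -> np.ndarray:
        """Hard labels for ARI scoring; overlap genes take their first
        module, background genes 0."""
        out = np.zeros(len(gene_ids), dtype=np.int64)
        for i, g in enumerate(gene_ids):
            mods = self.module_of.get(g, frozenset())
            if mods:
                out[i] = min(mods)
        return out

    def genes_of_kind(self, design: SimulationDesign, kind: str) -> list:
        keep = []
        for g, mods in self.module_of.items():
            if any(
                0 < m <= len(design.modules)
                and design.modules[m - 1].kind == kind
                for m in mods
            ):
                keep.append(g)
        return sorted(keep)


def default_design(seed: int = 0) -> SimulationDesign:
    """The desk-scale study: 200 genes x 100 samples, five planted
    30-gene modules (two linear, one threshold, one logarithmic, one
    GxE), 10 overlap genes and 40 background genes."""
    return SimulationDesign(
        n_samples=100,
        modules=[
            ModuleSpec(30, 1.0, "linear", 0.3),
            ModuleSpec(30, 1.0, "linear", 0.3),
            ModuleSpec(30, 1.0, "threshold", 0.3),
            ModuleSpec(30, 1.0, "logarithmic", 0.3),
            ModuleSpec(30, 1.0, "gxe", 0.1),
        ],
        n_overlap_genes=10,
        n_background_genes=40,
        condition_split=0.5,
        seed=seed,
    )


def _standardized(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd else 1.0)


def _response(kind: str, f: np.ndarray) -> np.ndarray:
    if kind in ("linear", "gxe"):
        return f
    if kind == "threshold":
        # high-threshold response: near-silent below the factor median,
        # switching on sharply above it
        return _standardized(1.0 / (1.0 + np.exp(-(f - np.median(f)) / 0.15)))
    if kind == "logarithmic":
        return _standardized(np.log(f - f.min() + 1.0))
    if kind == "quadratic":
        return _standardized(f**2)
    raise ValueError(kind)


def simulate_expression(design: SimulationDesign) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a planted-module expression matrix and its ground truth."""
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    n_treated = int(round(n * design.condition_split))
    conditions = np.zeros(n, dtype=np.int64)
    conditions[rng.choice(n, size=n_treated, replace=False)] = 1

    k = len(design.modules)
    factors = rng.standard_normal((k, n))
    factors = np.array([_standardized(f) for f in factors]) if k else np.empty((0, n))

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    module_of: dict = {}
    pair_types: dict = {}

    for mi, spec in enumerate(design.modules, start=1):
        f = factors[mi - 1]
        base = _response(spec.kind, f)
        members = []
        flipping: list[str] = []
        for gi in range(spec.size):
            gid = f"M{mi}_g{gi + 1}"
            if spec.kind == "gxe":
                if gi % 2 == 0:  # shifted: slope + in both conditions
                    profile = spec.loading * (f + GXE_SHIFT * conditions)
                else:  # flipping: opposite slope under treatment
                    profile = spec.loading * f * (1 - 2 * conditions)
                    flipping.append(gid)
            else:
                profile = spec.loading * base
            profile = profile + rng.normal(0.0, spec.noise_sd, size=n)
            gene_ids.append(gid)
            rows.append(profile)
            module_of[gid] = frozenset({mi})
            members.append(gid)
        flip = set(flipping)
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                a, b = members[ai], members[bi]
                if spec.kind == "gxe":
                    label = "gxe" if (a in flip) != (b in flip) else "linear"
                else:
                    label = spec.kind
                pair_types[frozenset((a, b))] = label

    if design.n_overlap_genes and k >= 2:
        # overlap genes load equally on two (non-GxE where possible) factors
        linear_idx = [i for i, s in enumerate(design.modules) if s.kind != "gxe"]
        pool = linear_idx if len(linear_idx) >= 2 else list(range(k))
        for gi in range(design.n_overlap_genes):
            a, b = pool[gi % len(pool)], pool[(gi + 1) % len(pool)]
            gid = f"OV_g{gi + 1}"
            noise = min(design.modules[a].noise_sd, design.modules[b].noise_sd)
            profile = 0.7 * factors[a] + 0.7 * factors[b]
            profile = profile + rng.normal(0.0, noise, size=n)
            gene_ids.append(gid)
            rows.append(profile)
            module_of[gid] = frozenset({a + 1, b + 1})

    for gi in range(design.n_background_genes):
        gid = f"BG_g{gi + 1}"
        gene_ids.append(gid)
        rows.append(rng.standard_normal(n))
        module_of[gid] = frozenset()

    sample_ids = [f"s{j + 1}" for j in range(n)]
    expr = ExpressionMatrix(gene_ids, sample_ids, np.vstack(rows))
    return expr, GroundTruth(module_of, pair_types, conditions, factors)


def simulate_scale_free(n_nodes: int, edges_per_node: int, seed: int = 0) -> EdgeList:
    """Preferential-attachment (Barabasi-Albert) graph as an EdgeList."""
    if not (n_nodes > edges_per_node >= 1):
        raise ValueError("need n_nodes > edges_per_node >= 1")
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=seed)
    width = len(str(n_nodes - 1))
    name = {i: f"n{str(i).zfill(width)}" for i in g.nodes}
    nodes = [name[i] for i in sorted(g.nodes)]
    edges = {frozenset((name[u], name[v])) for u, v in g.edges}
    return EdgeList(nodes, edges)


def simulate_ontology(
    n_terms: int, depth: int, genes, seed: int = 0
) -> AnnotationSet:
    """Random rooted DAG with propagated annotations.

    Gene sets are sized to span both traversal rules of the standard
    gene-class extraction: with enough genes the root exceeds 300 while
    several leaves fall below 30.
    """
    if n_terms < depth:
        raise ValueError("need n_terms >= depth")
    genes = sorted(set(genes))
    rng = np.random.default_rng(seed)
    term_ids = [f"T{str(i).zfill(3)}" for i in range(n_terms)]
    # assign terms to levels: root alone at level 0, at least one per level
    levels: list[list[str]] = [[term_ids[0]]]
    rest = term_ids[1:]
    cuts = sorted(
        rng.choice(len(rest) - 1, size=depth - 2, replace=False) + 1
    ) if depth > 2 and len(rest) > 1 else []
    pieces = np.split(np.array(rest), cuts) if depth > 1 else []
    levels.extend([list(p) for p in pieces if len(p)])
    parents: dict = {term_ids[0]: set()}
    for li in range(1, len(levels)):
        for t in levels[li]:
            n_par = 1 + int(rng.random() < 0.3)
            pool = levels[li - 1]
            chosen = rng.choice(len(pool), size=min(n_par, len(pool)), replace=False)
            parents[t] = {pool[c] for c in chosen}
    # direct annotations: leaves get log-uniform sized gene samples,
    # the root gets everything via propagation plus a few direct genes
    direct = {t: set() for t in term_ids}
    leaves = [t for t in term_ids if not any(t in parents[u] for u in parents)]
    for i, t in enumerate(leaves):
        if i == 0:
            size = min(10, len(genes))  # guaranteed undersized class
        else:
            size = int(np.exp(rng.uniform(np.log(5), np.log(max(6, len(genes) // 3)))))
            size = min(size, len(genes))
        chosen = rng.choice(len(genes), size=size, replace=False)
        direct[t] = {genes[c] for c in chosen}
    direct[term_ids[0]] = set(genes)  # root covers the dataset
    gene_sets = propagate_annotations(term_ids, parents, direct)
    return AnnotationSet(term_ids, parents, gene_sets)
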