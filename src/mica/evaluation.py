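"""Network-fitness statistics.

Bespoke measures for comparing module decompositions: rule-based
"standard gene classes" from an ontology DAG, a perplexity score over
the module-by-class confusion matrix, hypergeometric module enrichment
standing in for DAVID scores, the composite "usefulness" U, Fisher-exact
module stability between partitions, and a census of high-MIC pairs by
their Pearson correlation (the nonlinearity census).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssociationMatrix, ExpressionMatrix, ModulePartition
from .eigengene import stability_profile
from .icmg import threshold_membership
from .mic import mic_matrix, pearson_matrix


# ---------------------------------------------------------------------------
# ontology containers


@dataclass
class AnnotationSet:
    """Ontology DAG with per-term annotated gene sets.

    ``parents`` maps child term -> set of parent terms; ``gene_sets``
    hold fully propagated annotations (a gene annotated to a child
    belongs to every ancestor).
    """

    term_ids: list[str]
    parents: dict
    gene_sets: dict

    def __post_init__(self) -> None:
        self.gene_sets = {t: frozenset(g) for t, g in self.gene_sets.items()}
        self._children = {t: set() for t in self.term_ids}
        for child, pars in self.parents.items():
            for p in pars:
                self._children.setdefault(p, set()).add(child)
        # acyclicity check by iterative topological peel
        indeg = {t: len(self.parents.get(t, ())) for t in self.term_ids}
        queue = [t for t, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            t = queue.pop()
            seen += 1
            for ch in self._children.get(t, ()):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if seen != len(self.term_ids):
            raise ValueError("ontology graph contains a cycle")

    def children(self, term: str) -> set:
        return self._children.get(term, set())

    @property
    def roots(self) -> list[str]:
        return [t for t in self.term_ids if not self.parents.get(t)]


def load_obo(obo_path, annotation_path) -> AnnotationSet:
    """Build an AnnotationSet from an OBO file plus a gene->term TSV.

    The annotation table has two columns (gene, term), no header
    required if named columns are absent. Annotations are propagated
    child -> ancestors.
    """
    import obonet

    graph = obonet.read_obo(obo_path)
    # obonet edges point child -> parent via "is_a"
    term_ids = list(graph.nodes)
    parents = {
        t: {v for _, v, k in graph.out_edges(t, keys=True) if k == "is_a"}
        for t in term_ids
    }
    ann = pd.read_csv(annotation_path, sep="\t", header=None, comment="#")
    direct = {t: set() for t in term_ids}
    for gene, term in zip(ann.iloc[:, 0], ann.iloc[:, 1]):
        if term in direct:
            direct[str(term)].add(str(gene))
    gene_sets = propagate_annotations(term_ids, parents, direct)
    return AnnotationSet(term_ids, parents, gene_sets)


def propagate_annotations(term_ids, parents, direct) -> dict:
    """Propagate direct annotations to all ancestor terms."""
    children = {t: set() for t in term_ids}
    for child, pars in parents.items():
        for p in pars:
            children.setdefault(p, set()).add(child)
    full = {t: set(direct.get(t, ())) for t in term_ids}
    # process terms bottom-up (children before parents)
    order = []
    pending = {t: len(children.get(t, ())) for t in term_ids}
    queue = [t for t, d in pending.items() if d == 0]
    while queue:
        t = queue.pop()
        order.append(t)
        for p in parents.get(t, ()):
            pending[p] -= 1
            if pending[p] == 0:
                queue.append(p)
    for t in order:
        for p in parents.get(t, ()):
            full[p] |= full[t]
    return full


@dataclass
class GeneClassSet:
    """Standard gene classes: (term, gene set) pairs of moderate size."""

    classes: list

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def term_ids(self) -> list[str]:
        return [t for t, _ in self.classes]

    def as_dict(self) -> dict:
        return dict(self.classes)


def standard_gene_classes(
    ann: AnnotationSet,
    network_genes,
    min_size: int = 30,
    max_size: int = 300,
) -> GeneClassSet:
    """Rule-based DAG traversal yielding moderately sized gene classes.

    Descending from the root, a branch stops at a child with fewer than
    ``min_size`` network genes, emitting the parent unless the parent
    exceeds ``max_size`` (too broad to compartmentalize); a leaf emits
    itself under the same size cap. Emitted classes are deduplicated in
    traversal order.
    """
    network_genes = frozenset(network_genes)

    def count(term):
        return len(ann.gene_sets.get(term, frozenset()) & network_genes)

    emitted = []
    emitted_set = set()

    def emit(term):
        if term not in emitted_set and count(term) <= max_size:
            emitted_set.add(term)
            emitted.append(
                (term, ann.gene_sets[term] & network_genes)
            )

    visited = set()

    def visit(term):
        if term in visited:
            return
        visited.add(term)
        kids = sorted(ann.children(term))
        if not kids:
            emit(term)
            return
        stop_here = False
        for child in kids:
            if count(child) < min_size:
                stop_here = True
            else:
                visit(child)
        if stop_here:
            emit(term)

    roots = ann.roots
    any_large_root = False
    for root in roots:
        if count(root) < min_size:
            continue
        any_large_root = True
        visit(root)
    if not any_large_root:
        warnings.warn(
            "no ontology root reaches min_size network genes; "
            "class set is empty",
            stacklevel=2,
        )
    return GeneClassSet(emitted)


# ---------------------------------------------------------------------------
# perplexity


def perplexity(
    part: ModulePartition,
    classes: GeneClassSet,
    n_dataset_genes: int,
    events: str = "gene",
) -> tuple[float, float]:
    """Perplexity of the module-by-class confusion matrix.

    Co-occurrence counts are gene-level: each placed gene contributes
    one event per (module it occupies, class containing it) pair. The
    raw score is 2**(-sum_l log2 Phat(c_l | r_l) / N) over those N
    events with row-normalized probabilities Phat; ``events="cell"``
    instead counts each nonzero confusion cell once. The normalized
    score multiplies by placed / n_dataset_genes so methods that leave
    genes unplaced do not gain an unfair advantage.
    """
    class_map = classes.as_dict()
    class_ids = classes.term_ids
    cindex = {t: i for i, t in enumerate(class_ids)}
    counts = np.zeros((part.n_modules, len(class_ids)))
    placed = 0
    for gene, ass in zip(part.gene_ids, part.assignments):
        if ass:
            placed += 1
        for m in ass:
            for t, gene_set in class_map.items():
                if gene in gene_set:
                    counts[m - 1, cindex[t]] += 1
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix: no gene is in both a module and a class")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(row_sums > 0, counts / row_sums, 0.0)
    nz = counts > 0
    if events == "gene":
        n_events = counts[nz].sum()
        loglik = (counts[nz] * np.log2(phat[nz])).sum()
    elif events == "cell":
        n_events = nz.sum()
        loglik = np.log2(phat[nz]).sum()
    else:
        raise ValueError("events must be 'gene' or 'cell'")
    raw = float(2.0 ** (-loglik / n_events))
    normalized = raw * placed / n_dataset_genes
    return raw, normalized


# ---------------------------------------------------------------------------
# enrichment + usefulness


@dataclass
class ModuleEnrichment:
    """Per-module best enrichment over annotation terms."""

    scores: dict  # module -> max -log10 hypergeometric p
    best_terms: dict  # module -> term attaining the max
    pvalues: pd.DataFrame  # module x term one-sided p


def module_enrichment(
    part: ModulePartition, classes: GeneClassSet | AnnotationSet, universe
) -> ModuleEnrichment:
    """Hypergeometric over-representation of terms in each module.

    The per-module score is the maximum -log10 p over terms, the local
    stand-in for a DAVID enrichment score. Empty modules score 0.
    """
    universe = frozenset(universe)
    n_univ = len(universe)
    if isinstance(classes, AnnotationSet):
        term_sets = {t: s & universe for t, s in classes.gene_sets.items()}
    else:
        term_sets = {t: s & universe for t, s in classes.as_dict().items()}
    term_ids = sorted(term_sets)
    scores, best_terms = {}, {}
    pmat = np.ones((part.n_modules, len(term_ids)))
    for m in range(1, part.n_modules + 1):
        genes = frozenset(part.module_genes(m)) & universe
        if not genes:
            scores[m] = 0.0
            best_terms[m] = None
            continue
        best_p, best_t = 1.0, None
        for ti, t in enumerate(term_ids):
            k_term = len(term_sets[t])
            overlap = len(genes & term_sets[t])
            p = float(
                stats.hypergeom.sf(overlap - 1, n_univ, k_term, len(genes))
            )
            pmat[m - 1, ti] = p
            if p < best_p:
                best_p, best_t = p, t
        scores[m] = float(-np.log10(max(best_p, 1e-300)))
        best_terms[m] = best_t
    pvals = pd.DataFrame(
        pmat, index=range(1, part.n_modules + 1), columns=term_ids
    )
    return ModuleEnrichment(scores, best_terms, pvals)


def usefulness(scores_and_sizes, n_unplaced: int) -> float:
    """Composite module-quality score.

    U = sum_i score_i / log2(N_i) - log10(M) with N_i the module sizes
    and M the unplaced-gene count. Singleton modules are skipped with a
    warning (log2 1 = 0); M = 0 is treated as no penalty (M = 1).
    """
    m = n_unplaced
    if m < 0:
        raise ValueError("unplaced count must be nonnegative")
    if m == 0:
        warnings.warn("no unplaced genes; usefulness penalty set to 0", stacklevel=2)
        m = 1
    total = 0.0
    for score, n_i in scores_and_sizes:
        if n_i < 2:
            warnings.warn(
                f"module of size {n_i} skipped in usefulness (log2 N = 0)",
                stacklevel=2,
            )
            continue
        total += score / np.log2(n_i)
    return float(total - np.log10(m))


def usefulness_of_partition(
    part: ModulePartition, classes: GeneClassSet | AnnotationSet, universe
) -> float:
    """Usefulness computed from a partition's own enrichment and sizes."""
    enr = module_enrichment(part, classes, universe)
    pairs = [
        (enr.scores[m], len(part.module_genes(m)))
        for m in range(1, part.n_modules + 1)
        if len(part.module_genes(m)) > 0
    ]
    return usefulness(pairs, part.n_unplaced)


# ---------------------------------------------------------------------------
# module stability


@dataclass
class StabilityTable:
    """Module-overlap counts and Fisher-exact preservation p-values."""

    modules_a: list[int]
    modules_b: list[int]
    overlap: pd.DataFrame
    pvalue: pd.DataFrame


def module_stability(
    part_a: ModulePartition, part_b: ModulePartition, universe
) -> StabilityTable:
    """One-sided Fisher exact test on every module-pair overlap.

    For modules A_i, B_j over a common gene universe the 2x2 table is
    (in both, A only, B only, neither); the one-sided alternative tests
    over-representation, i.e. preservation of A_i inside B_j.
    """
    universe = frozenset(universe)
    n = len(universe)
    mods_a = list(range(1, part_a.n_modules + 1))
    mods_b = list(range(1, part_b.n_modules + 1))
    ov = np.zeros((len(mods_a), len(mods_b)), dtype=int)
    pv = np.ones((len(mods_a), len(mods_b)))
    for ai, a in enumerate(mods_a):
        ga = frozenset(part_a.module_genes(a)) & universe
        for bi, b in enumerate(mods_b):
            gb = frozenset(part_b.module_genes(b)) & universe
            both = len(ga & gb)
            table = [
                [both, len(ga) - both],
                [len(gb) - both, n - len(ga) - len(gb) + both],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            ov[ai, bi] = both
            pv[ai, bi] = p
    return StabilityTable(
        mods_a,
        mods_b,
        pd.DataFrame(ov, index=mods_a, columns=mods_b),
        pd.DataFrame(pv, index=mods_a, columns=mods_b),
    )


# ---------------------------------------------------------------------------
# nonlinearity census


@dataclass
class CensusResult:
    """Pearson profile of high-MIC gene pairs."""

    n_high_mic: int
    pearson_abs_values: np.ndarray
    frac_low: float
    frac_high: float
    pairs: list = field(default_factory=list)


def nonlinearity_census(
    expr: ExpressionMatrix,
    mic_cut: float = 0.9,
    low_cut: float = 0.6,
    high_cut: float = 0.9,
    subsample_to: int | None = None,
    seed: int = 0,
    mic: AssociationMatrix | None = None,
    pearson: AssociationMatrix | None = None,
) -> CensusResult:
    """Census of pairs with MIC above ``mic_cut`` by their |Pearson r|.

    Reports the fraction of high-MIC pairs with |r| below ``low_cut``
    (nonlinear) and above ``high_cut`` (near-perfectly linear).
    Precomputed association matrices may be passed to avoid recomputing;
    ``subsample_to`` uniformly subsamples the census (seeded) to match
    a reference census size.
    """
    if mic is None:
        mic = mic_matrix(expr)
    if pearson is None:
        pearson = pearson_matrix(expr, absolute=True)
    ids = mic.gene_ids
    iu, ju = np.triu_indices(mic.n_genes, k=1)
    hit = mic.scores[iu, ju] > mic_cut
    r_vals = np.abs(pearson.scores[iu[hit], ju[hit]])
    pairs = [(ids[i], ids[j]) for i, j in zip(iu[hit], ju[hit])]
    if len(pairs) == 0:
        warnings.warn("no pair passes the MIC cutoff; empty census", stacklevel=2)
        return CensusResult(0, np.array([]), np.nan, np.nan, [])
    if subsample_to is not None and subsample_to < len(pairs):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=subsample_to, replace=False)
        keep.sort()
        r_vals = r_vals[keep]
        pairs = [pairs[k] for k in keep]
    return CensusResult(
        len(pairs),
        r_vals,
        float((r_vals < low_cut).mean()),
        float((r_vals > high_cut).mean()),
        pairs,
    )


# ---------------------------------------------------------------------------
# optimal cutoff scan


def optimal_cutoff_scan(
    expr: ExpressionMatrix,
    mm,
    classes: GeneClassSet | AnnotationSet,
    universe,
    cutoffs,
    stability_floor: float = 0.99,
) -> tuple[float, dict]:
    """Pick the MM cutoff maximizing usefulness among stable cutoffs.

    Cutoffs whose mean eigengene correlation (to the other cutoffs and
    to the weighted PCA) falls below ``stability_floor`` are excluded;
    if none pass, the scan covers all cutoffs with a warning. Ties in
    usefulness break toward the lowest cutoff.
    """
    cutoffs = [float(c) for c in cutoffs]
    profile = stability_profile(expr, mm, cutoffs)
    stable = [
        c
        for i, c in enumerate(cutoffs)
        if profile.mean_correlation(i) >= stability_floor
    ]
    if not stable:
        warnings.warn(
            "no cutoff passes the stability floor; scanning all cutoffs",
            stacklevel=2,
        )
        stable = cutoffs
    u_by_cutoff = {}
    for c in stable:
        part = threshold_membership(mm, c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u_by_cutoff[c] = usefulness_of_partition(part, classes, universe)
    best = max(sorted(u_by_cutoff), key=lambda c: (u_by_cutoff[c], -c))
    return best, u_by_cutoff
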