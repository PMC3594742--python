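import numpy as np
import pytest
from scipy import stats

from mica.datatypes import ModulePartition
from mica.evaluation import (
    AnnotationSet,
    GeneClassSet,
    module_enrichment,
    module_stability,
    nonlinearity_census,
    optimal_cutoff_scan,
    perplexity,
    standard_gene_classes,
    usefulness,
    usefulness_of_partition,
)

from .conftest import gxe_pair, make_expr


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestStandardGeneClasses:
    def _ann(self, tree, sets):
        """tree: child -> parent; sets: term -> genes."""
        terms = sorted(set(tree) | set(p for p in tree.values() if p) | set(sets))
        parents = {t: ({tree[t]} if tree.get(t) else set()) for t in terms}
        return AnnotationSet(terms, parents, sets)

    def test_flat_ontology_all_emitted(self):
        g = genes("g", 200)
        sets = {"root": set(g)}
        tree = {"root": None}
        for i in range(4):
            t = f"t{i}"
            tree[t] = "root"
            sets[t] = set(g[i * 50 : (i + 1) * 50])
        ann = self._ann(tree, sets)
        classes = standard_gene_classes(ann, set(g), 30, 300)
        assert set(classes.term_ids) == {"t0", "t1", "t2", "t3"}

    def test_hand_traced_stop_rule(self):
        # root(400) -> A(200) -> {A1(25), A2(40)}: A emitted via A1's
        # stop rule, A2 explored and emitted as a leaf, root not emitted
        g = genes("g", 400)
        sets = {
            "root": set(g),
            "A": set(g[:200]),
            "A1": set(g[:25]),
            "A2": set(g[25:65]),
        }
        tree = {"root": None, "A": "root", "A1": "A", "A2": "A"}
        classes = standard_gene_classes(self._ann(tree, sets), set(g), 30, 300)
        assert set(classes.term_ids) == {"A", "A2"}

    def test_oversized_parent_omitted(self):
        g = genes("g", 400)
        sets = {"root": set(g), "B": set(g[:350]), "B1": set(g[:10])}
        tree = {"root": None, "B": "root", "B1": "B"}
        classes = standard_gene_classes(self._ann(tree, sets), set(g), 30, 300)
        assert "B" not in classes.term_ids

    def test_small_root_warns_empty(self):
        g = genes("g", 10)
        ann = self._ann({"root": None}, {"root": set(g)})
        with pytest.warns(UserWarning, match="root"):
            classes = standard_gene_classes(ann, set(g), 30, 300)
        assert len(classes) == 0


class TestPerplexity:
    def _partition_and_classes(self, counts):
        """Build genes realizing a given module x class count matrix."""
        counts = np.asarray(counts)
        gene_ids, assignments, class_sets = [], [], {}
        gi = 0
        for r in range(counts.shape[0]):
            for c in range(counts.shape[1]):
                for _ in range(counts[r, c]):
                    gid = f"g{gi}"
                    gi += 1
                    gene_ids.append(gid)
                    assignments.append(frozenset({r + 1}))
                    class_sets.setdefault(f"c{c}", set()).add(gid)
        part = ModulePartition(gene_ids, assignments, counts.shape[0])
        classes = GeneClassSet(sorted(class_sets.items()))
        return part, classes, len(gene_ids)

    def test_diagonal_confusion_gives_one(self):
        part, classes, n = self._partition_and_classes(np.diag([5, 7, 3]))
        raw, norm = perplexity(part, classes, n)
        assert raw == pytest.approx(1.0, abs=1e-12)
        assert norm == pytest.approx(1.0, abs=1e-12)  # all genes placed

    def test_uniform_over_four_classes_gives_four(self):
        part, classes, n = self._partition_and_classes(np.full((3, 4), 5))
        raw, _ = perplexity(part, classes, n)
        assert raw == pytest.approx(4.0, abs=1e-12)

    def test_matches_direct_formula_evaluation(self):
        counts = np.array([[6, 2, 0], [1, 1, 8]])
        part, classes, n = self._partition_and_classes(counts)
        raw, norm = perplexity(part, classes, n)
        # independent evaluation of 2**(-sum c*log2(phat) / N)
        phat = counts / counts.sum(axis=1, keepdims=True)
        ll = sum(
            counts[r, c] * np.log2(phat[r, c])
            for r in range(2)
            for c in range(3)
            if counts[r, c] > 0
        )
        expected = 2 ** (-ll / counts.sum())
        assert raw == pytest.approx(expected, abs=1e-12)
        assert norm == pytest.approx(expected, abs=1e-12)

    def test_raw_at_least_one_and_unplaced_normalization(self):
        counts = np.array([[3, 1], [2, 2]])
        part, classes, n = self._partition_and_classes(counts)
        # add unplaced genes: normalized shrinks, raw unchanged
        part2 = ModulePartition(
            part.gene_ids + ["extra1", "extra2"],
            list(part.assignments) + [frozenset(), frozenset()],
            part.n_modules,
        )
        raw1, norm1 = perplexity(part, classes, n)
        raw2, norm2 = perplexity(part2, classes, n + 2)
        assert raw1 >= 1.0
        assert raw2 == pytest.approx(raw1, abs=1e-12)
        assert norm2 == pytest.approx(raw1 * n / (n + 2), abs=1e-12)

    def test_cell_events_agree_on_closed_forms(self):
        part, classes, n = self._partition_and_classes(np.diag([5, 7]))
        assert perplexity(part, classes, n, events="cell")[0] == pytest.approx(1.0)
        part, classes, n = self._partition_and_classes(np.full((2, 4), 3))
        assert perplexity(part, classes, n, events="cell")[0] == pytest.approx(4.0)


class TestModuleEnrichment:
    def test_perfect_enrichment_attains_max(self):
        univ = genes("g", 100)
        term_sets = {"rare": set(univ[:10]), "common": set(univ[:60])}
        classes = GeneClassSet(sorted(term_sets.items()))
        part = ModulePartition(
            univ, [frozenset({1})] * 10 + [frozenset()] * 90, 1
        )
        enr = module_enrichment(part, classes, set(univ))
        assert enr.best_terms[1] == "rare"
        p_exact = stats.hypergeom.sf(9, 100, 10, 10)
        assert enr.scores[1] == pytest.approx(-np.log10(p_exact), abs=1e-9)

    def test_random_modules_score_below_perfect(self):
        rng = np.random.default_rng(1)
        univ = genes("g", 100)
        term_sets = {"t": set(univ[:10])}
        classes = GeneClassSet(sorted(term_sets.items()))
        perfect = -np.log10(stats.hypergeom.sf(9, 100, 10, 10))
        scores = []
        for _ in range(200):
            pick = set(rng.choice(univ, 10, replace=False))
            part = ModulePartition(
                univ,
                [frozenset({1}) if g in pick else frozenset() for g in univ],
                1,
            )
            scores.append(module_enrichment(part, classes, set(univ)).scores[1])
        assert np.median(scores) < perfect

    def test_hypergeometric_tail_sum_oracle(self):
        # module 10, term 10, overlap 5, universe 100
        univ = genes("g", 100)
        term_sets = {"t": set(univ[:10])}
        classes = GeneClassSet(sorted(term_sets.items()))
        module = set(univ[5:15])  # overlap = 5
        part = ModulePartition(
            univ, [frozenset({1}) if g in module else frozenset() for g in univ], 1
        )
        enr = module_enrichment(part, classes, set(univ))
        tail = sum(
            stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11)
        )
        assert enr.scores[1] == pytest.approx(-np.log10(tail), abs=1e-9)

    def test_empty_module_scores_zero(self):
        univ = genes("g", 20)
        classes = GeneClassSet([("t", frozenset(univ[:5]))])
        part = ModulePartition(univ, [frozenset()] * 20, 2)
        enr = module_enrichment(part, classes, set(univ))
        assert enr.scores[1] == 0.0 and enr.scores[2] == 0.0


class TestUsefulness:
    def test_round_number_closed_forms(self):
        assert usefulness([(4.0, 16)], 10) == pytest.approx(0.0, abs=1e-12)
        assert usefulness([(3.0, 8), (6.0, 64)], 10) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_score_and_unplaced(self):
        base = usefulness([(3.0, 8), (2.0, 16)], 10)
        assert usefulness([(4.0, 8), (2.0, 16)], 10) > base
        assert usefulness([(3.0, 8), (2.0, 16)], 100) < base

    def test_singleton_skipped_and_zero_unplaced(self):
        with pytest.warns(UserWarning):
            v = usefulness([(5.0, 1), (4.0, 16)], 10)
        assert v == pytest.approx(1.0 - 1.0, abs=1e-12)
        with pytest.warns(UserWarning):
            assert usefulness([(4.0, 16)], 0) == pytest.approx(1.0, abs=1e-12)


class TestModuleStability:
    def _part(self, labels, n_modules):
        ids = genes("g", len(labels))
        return ModulePartition(
            ids,
            [frozenset({l}) if l else frozenset() for l in labels],
            n_modules,
        )

    def test_identical_partitions_extremes(self):
        labels = [1] * 10 + [2] * 10 + [0] * 5
        a = self._part(labels, 2)
        table = module_stability(a, a, set(a.gene_ids))
        assert table.pvalue.iat[0, 0] < 1e-4
        assert table.pvalue.iat[1, 1] < 1e-4
        assert table.overlap.iat[0, 1] == 0
        assert table.pvalue.iat[0, 1] == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(2)
        la = rng.integers(1, 4, 30)
        lb = rng.integers(1, 3, 30)
        a, b = self._part(la, 3), self._part(lb, 2)
        t_ab = module_stability(a, b, set(a.gene_ids))
        t_ba = module_stability(b, a, set(a.gene_ids))
        np.testing.assert_allclose(
            t_ab.pvalue.to_numpy(), t_ba.pvalue.to_numpy().T, atol=1e-12
        )

    def test_matches_hypergeometric_tail(self):
        labels_a = [1] * 10 + [0] * 90
        labels_b = [0] * 5 + [1] * 10 + [0] * 85
        a, b = self._part(labels_a, 1), self._part(labels_b, 1)
        table = module_stability(a, b, set(a.gene_ids))
        tail = sum(stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert table.overlap.iat[0, 0] == 5
        assert table.pvalue.iat[0, 0] == pytest.approx(tail, rel=1e-9)


class TestNonlinearityCensus:
    def test_all_linear_data_no_low_pearson(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal(60)
        expr = make_expr(f + rng.normal(0, 0.02, (6, 60)))
        census = nonlinearity_census(expr, mic_cut=0.9)
        assert census.n_high_mic > 0
        assert census.frac_low == 0.0

    def test_planted_gxe_pairs_detected(self):
        x, y, _ = gxe_pair(n=100, noise=0.05, seed=4)
        rng = np.random.default_rng(5)
        vals = np.vstack([x, y, rng.standard_normal((3, 100))])
        expr = make_expr(vals)
        census = nonlinearity_census(expr, mic_cut=0.8)
        assert ("g1", "g2") in census.pairs
        idx = census.pairs.index(("g1", "g2"))
        assert census.pearson_abs_values[idx] < 0.3

    def test_subsample_larger_than_census_is_identity(self):
        rng = np.random.default_rng(6)
        f = rng.standard_normal(50)
        expr = make_expr(f + rng.normal(0, 0.05, (4, 50)))
        full = nonlinearity_census(expr, mic_cut=0.8)
        sub = nonlinearity_census(expr, mic_cut=0.8, subsample_to=10_000)
        assert sub.n_high_mic == full.n_high_mic
        np.testing.assert_array_equal(sub.pearson_abs_values, full.pearson_abs_values)

    def test_census_monotone_in_mic_cut(self):
        rng = np.random.default_rng(7)
        expr = make_expr(rng.standard_normal((8, 40)))
        prev = None
        for cut in (0.2, 0.4, 0.6, 0.8):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n = nonlinearity_census(expr, mic_cut=cut).n_high_mic
            if prev is not None:
                assert n <= prev
            prev = n


class TestOptimalCutoffScan:
    def test_matches_exhaustive_per_cutoff_evaluation(self):
        from mica.datatypes import MembershipMatrix
        from mica.icmg import threshold_membership

        rng = np.random.default_rng(8)
        n_samples, per_mod = 40, 15
        blocks, mm_rows = [], []
        for k in range(3):
            f = rng.standard_normal(n_samples)
            blocks.append(f + rng.normal(0, 0.2, (per_mod, n_samples)))
            for _ in range(per_mod):
                main = rng.uniform(0.55, 0.9)
                rest = rng.dirichlet(np.ones(2)) * (1 - main)
                row = np.empty(3)
                row[k] = main
                row[[i for i in range(3) if i != k]] = rest
                mm_rows.append(row)
        expr = make_expr(np.vstack(blocks))
        mm = MembershipMatrix(expr.gene_ids, np.array(mm_rows))
        univ = set(expr.gene_ids)
        classes = GeneClassSet(
            [
                (f"t{k}", frozenset(expr.gene_ids[k * per_mod : (k + 1) * per_mod]))
                for k in range(3)
            ]
        )
        cutoffs = [0.3, 0.4, 0.5, 0.6]
        best, u = optimal_cutoff_scan(
            expr, mm, classes, univ, cutoffs, stability_floor=0.0
        )
        # independent exhaustive evaluation over the same cutoffs
        import warnings

        expected = {}
        for c in cutoffs:
            part = threshold_membership(mm, c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                expected[c] = usefulness_of_partition(part, classes, univ)
        assert u == pytest.approx(expected)
        exp_best = min(
            (c for c in cutoffs if expected[c] == max(expected.values()))
        )
        assert best == exp_best

    def test_tie_breaks_to_lowest_cutoff(self):
        # identical membership sets at both cutoffs -> identical U -> tie
        from mica.datatypes import MembershipMatrix

        rng = np.random.default_rng(9)
        expr = make_expr(rng.standard_normal((6, 30)))
        mm_arr = np.column_stack([np.full(6, 0.9), np.full(6, 0.1)])
        mm = MembershipMatrix(expr.gene_ids, mm_arr)
        classes = GeneClassSet([("t", frozenset(expr.gene_ids[:3]))])
        best, u = optimal_cutoff_scan(
            expr, mm, classes, set(expr.gene_ids), [0.3, 0.5], stability_floor=0.0
        )
        assert len(set(round(v, 12) for v in u.values())) == 1
        assert best == 0.3
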