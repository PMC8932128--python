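"""Precision-recall evaluation: AP, curves, recall@k, tie policies, tasks."""

import numpy as np
import pytest

from rhythmrank import (
    LabelSet,
    average_precision,
    pr_curve,
    rank_genes,
    recall_at_k,
    run_task,
)


def _ranked_from_labels(label_string, scores=None):
    """Build a ranking from a +/- string; distinct descending scores unless given."""
    genes = [f"g{i}" for i in range(len(label_string))]
    if scores is None:
        scores = list(range(len(genes), 0, -1))
    ranked = rank_genes(dict(zip(genes, map(float, scores))), "descending")
    labels = LabelSet(tuple(genes),
                      frozenset(g for g, c in zip(genes, label_string) if c == "+"))
    return ranked, labels


class TestAveragePrecision:
    def test_perfect_ranking_is_one(self):
        ranked, labels = _ranked_from_labels("+++" + "-" * 20)
        assert average_precision(ranked, labels).average_precision == 1.0

    def test_plus_minus_plus(self):
        # precisions at the two positives: 1/1 and 2/3 -> AP = 5/6
        ranked, labels = _ranked_from_labels("+-+")
        assert average_precision(ranked, labels).average_precision == pytest.approx(5 / 6)

    def test_no_positives_is_error(self):
        ranked, labels = _ranked_from_labels("---")
        with pytest.raises(ValueError, match="no positives"):
            average_precision(ranked, labels)

    def test_universe_mismatch_lists_ids(self):
        ranked, _ = _ranked_from_labels("+-")
        labels = LabelSet(("g0", "g1", "gx"), frozenset({"g0"}))
        with pytest.raises(ValueError, match="gx"):
            average_precision(ranked, labels)

    def test_random_ranking_mean_matches_exact_expectation(self, rng):
        # the exact mean AP of a random ranking; C/N is only its large-C limit
        from rhythmrank.evaluation import expected_random_ap

        N, C, reps = 120, 10, 4000
        hits = np.zeros((reps, N), dtype=bool)
        hits[:, :C] = True
        hits = rng.permuted(hits, axis=1)
        prec = np.cumsum(hits, axis=1) / np.arange(1, N + 1)
        aps = np.where(hits, prec, 0).sum(axis=1) / C
        se = aps.std(ddof=1) / np.sqrt(reps)
        assert abs(aps.mean() - expected_random_ap(C, N)) < 3 * se
        assert expected_random_ap(C, N) > C / N  # strictly above the base rate

    def test_fully_tied_ranking_expected_ap_equals_random_mean(self):
        # one giant tie block under the expected policy IS the random classifier
        from rhythmrank.evaluation import expected_random_ap

        genes = [f"g{i}" for i in range(60)]
        ranked = rank_genes({g: 0.0 for g in genes}, "ascending")
        labels = LabelSet(tuple(genes), frozenset(genes[:7]))
        res = average_precision(ranked, labels, "expected")
        assert res.average_precision == pytest.approx(expected_random_ap(7, 60), abs=1e-12)

    def test_matches_sklearn_on_tie_free_rankings(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(10):
            scores = rng.normal(size=50)
            y = rng.random(50) < 0.2
            if not y.any():
                continue
            genes = [f"g{i}" for i in range(50)]
            ranked = rank_genes(dict(zip(genes, scores)), "descending")
            labels = LabelSet(tuple(genes), frozenset(np.array(genes)[y]))
            ours = average_precision(ranked, labels).average_precision
            theirs = average_precision_score(y, scores)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        y = np.zeros(40, bool)
        y[:6] = True
        genes = [f"g{i}" for i in range(40)]
        labels = LabelSet(tuple(genes), frozenset(np.array(genes)[y]))
        a = average_precision(rank_genes(dict(zip(genes, scores)), "descending"), labels)
        b = average_precision(
            rank_genes(dict(zip(genes, np.exp(scores))), "descending"), labels
        )
        assert a.average_precision == pytest.approx(b.average_precision, abs=1e-12)


class TestPrCurve:
    def test_perfect_ranking_precision_all_one(self):
        ranked, labels = _ranked_from_labels("++--")
        res = pr_curve(ranked, labels)
        np.testing.assert_allclose(res.precisions, 1.0)
        np.testing.assert_allclose(res.recalls, [0.5, 1.0])
        assert res.recalls[-1] == 1.0

    def test_single_tie_block_flat_at_baseline(self):
        genes = [f"g{i}" for i in range(20)]
        ranked = rank_genes({g: 1.0 for g in genes}, "ascending")
        labels = LabelSet(tuple(genes), frozenset(genes[:4]))
        res = pr_curve(ranked, labels, "expected")
        np.testing.assert_allclose(res.precisions, labels.baseline)

    def test_reversed_perfect_pessimistic_first_precision(self):
        # all N-C negatives first: the first positive appears at rank N-C+1
        ranked, labels = _ranked_from_labels("---++")
        res = pr_curve(ranked, labels, "pessimistic")
        assert res.precisions[0] == pytest.approx(1 / (5 - 2 + 1))

    def test_recall_nondecreasing(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ranked = rank_genes(
            {g: float(rng.integers(0, 8)) for g in genes}, "ascending"
        )
        labels = LabelSet(tuple(genes), frozenset(rng.choice(genes, 9, replace=False)))
        res = pr_curve(ranked, labels)
        assert np.all(np.diff(res.recalls) >= -1e-12)
        assert res.baseline == labels.baseline


class TestRecallAtK:
    def test_k_at_least_n_gives_one(self):
        ranked, labels = _ranked_from_labels("+--+-")
        frac, count = recall_at_k(ranked, labels, 5)
        assert frac == 1.0 and count == 2

    def test_no_positives_in_top_k(self):
        ranked, labels = _ranked_from_labels("--++")
        frac, _ = recall_at_k(ranked, labels, 2)
        assert frac == 0.0

    def test_straddling_block_expected_share(self):
        # 1 distinct leader, then a block of 4 (2 positive) straddling k=3:
        # expected positives inside = 2 * 2/4 = 1
        ranked, labels = _ranked_from_labels("-+-+-", scores=[5, 1, 1, 1, 1])
        frac, count = recall_at_k(ranked, labels, 3, "expected")
        assert count == pytest.approx(1.0)
        lo = recall_at_k(ranked, labels, 3, "pessimistic")[1]
        hi = recall_at_k(ranked, labels, 3, "optimistic")[1]
        assert lo == 0.0 and hi == 2.0

    def test_fraction_example(self):
        ranked, labels = _ranked_from_labels("+" * 13 + "-" * 12 + "+" * 4 + "-" * 278)
        frac, count = recall_at_k(ranked, labels, 25)
        assert count == 13 and frac == pytest.approx(13 / 17)
        assert round(100 * frac, 1) == 76.5


class TestTiePolicies:
    def test_bracket_and_monte_carlo_expectation(self, rng):
        N, C = 50, 8
        genes = [f"g{i}" for i in range(N)]
        for _ in range(20):
            scores = {g: float(rng.integers(0, 5)) for g in genes}
            pos = frozenset(rng.choice(genes, C, replace=False))
            labels = LabelSet(tuple(genes), pos)
            ranked = rank_genes(scores, "ascending")
            pess = average_precision(ranked, labels, "pessimistic").average_precision
            expe = average_precision(ranked, labels, "expected").average_precision
            opti = average_precision(ranked, labels, "optimistic").average_precision
            assert pess <= expe + 1e-12 <= opti + 2e-12
            # MC oracle: shuffle within tie blocks
            ids = np.array(ranked.gene_ids)
            aps = []
            for _ in range(2000):
                order = ids.copy()
                for s, e in ranked.tie_blocks:
                    order[s:e] = rng.permutation(order[s:e])
                hits = np.fromiter((g in pos for g in order), bool)
                prec = np.cumsum(hits) / np.arange(1, N + 1)
                aps.append(prec[hits].sum() / C)
            assert abs(np.mean(aps) - expe) < 0.006


class TestRunTask:
    def test_three_tasks_schema(self, small_sim):
        from rhythmrank.pipeline import score_dataset

        sc = score_dataset(small_sim.matrix, n_null=200, seed=3)
        for task in ("core_in_tfs", "core_in_all", "tf_in_all"):
            df = run_task(sc, small_sim.core.positives, small_sim.tfs.positives, task)
            assert len(df) == 8
            assert (df.ap_pessimistic <= df.ap_expected + 1e-12).all()
            assert (df.baseline == df.n_positives / df.n_universe).all()

    def test_smaller_universe_does_not_hurt_ap(self, small_sim):
        from rhythmrank.pipeline import score_dataset

        sc = score_dataset(small_sim.matrix, n_null=200, seed=3)
        in_tfs = run_task(sc, small_sim.core.positives, small_sim.tfs.positives,
                          "core_in_tfs", metrics=["per_reg"]).ap.iloc[0]
        in_all = run_task(sc, small_sim.core.positives, small_sim.tfs.positives,
                          "core_in_all", metrics=["per_reg"]).ap.iloc[0]
        assert in_tfs >= in_all - 1e-9

    def test_missing_core_gene_warns(self, small_sim):
        from rhythmrank.pipeline import score_dataset

        sc = score_dataset(small_sim.matrix, n_null=50, seed=3)
        core = set(small_sim.core.positives) | {"NOT_A_GENE"}
        with pytest.warns(UserWarning, match="absent"):
            run_task(sc, core, small_sim.tfs.positives, "core_in_all",
                     metrics=["per_reg"])

    def test_empty_tf_list_is_error(self, small_sim):
        from rhythmrank.pipeline import score_dataset

        sc = score_dataset(small_sim.matrix, n_null=50, seed=3)
        with pytest.raises(ValueError, match="TF"):
            run_task(sc, small_sim.core.positives, [], "core_in_tfs")
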