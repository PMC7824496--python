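import numpy as np
import pytest

from mnbdr import auc01, evaluate, permutation_pvalue, roc_auc
from mnbdr.io import BenchmarkStandard


def pairwise_auc_oracle(scores, labels):
    """Mann–Whitney probability by explicit pairwise comparison."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def standard_from(positive_pairs, universe):
    return BenchmarkStandard(pairs=frozenset(positive_pairs),
                             drug_universe=frozenset(universe))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 2, 1], [True, False, False]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 1, 1, 1], [True, False, True, False]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 10, size=30).astype(float)  # forces ties
            labels = rng.random(30) < 0.3
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels))

    def test_negation_complements(self, rng):
        scores = rng.normal(size=25)  # tie-free
        labels = np.arange(25) < 8
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


class TestAuc01:
    def test_perfect_ranking_hits_ceiling(self):
        scores = np.arange(20, 0, -1, dtype=float)
        labels = np.arange(20) < 5
        assert auc01(scores, labels) == pytest.approx(0.1)

    def test_diagonal_roc_gives_triangle_area(self):
        scores = np.ones(40)
        labels = np.arange(40) < 10
        assert auc01(scores, labels) == pytest.approx(0.005)

    def test_bounded_by_strip(self, rng):
        for _ in range(30):
            scores = rng.normal(size=40)
            labels = rng.random(40) < 0.3
            if labels.all() or not labels.any():
                continue
            a = auc01(scores, labels)
            assert 0.0 <= a <= 0.1 + 1e-12

    def test_matches_dense_threshold_integration(self, rng):
        for _ in range(20):
            scores = rng.normal(size=50)
            labels = rng.random(50) < 0.4
            if labels.all() or not labels.any():
                continue
            # brute-force ROC: sweep every distinct score as a threshold,
            # then trapezoid-integrate the curve clipped at FPR = 0.1
            thresholds = np.unique(scores)[::-1]
            n_pos, n_neg = labels.sum(), (~labels).sum()
            fpr = [0.0]
            tpr = [0.0]
            for th in thresholds:
                sel = scores >= th
                tpr.append((sel & labels).sum() / n_pos)
                fpr.append((sel & ~labels).sum() / n_neg)
            fpr, tpr = np.array(fpr), np.array(tpr)
            tpr_at = np.interp(0.1, fpr, tpr)
            keep = fpr <= 0.1
            area = np.trapezoid(np.append(tpr[keep], tpr_at),
                                np.append(fpr[keep], 0.1))
            assert auc01(scores, labels) == pytest.approx(area, abs=1e-12)


class TestPermutationPValue:
    def _rankings(self, rng, n_drugs=20, separated=True):
        drugs = [f"d{i:02d}" for i in range(n_drugs)]
        scores = (np.arange(n_drugs, 0, -1, dtype=float) if separated
                  else rng.normal(size=n_drugs))
        return {"disX": list(zip(drugs, scores))}, drugs

    def test_observed_above_all_null_draws(self, rng):
        rankings, drugs = self._rankings(rng, separated=True)
        std = standard_from({(d, "disX") for d in drugs[:4]}, drugs)
        p = permutation_pvalue(rankings, std, metric="auc", n_perm=9, rng_seed=0)
        assert p.empirical == pytest.approx(0.1)

    def test_null_observed_sits_near_median(self, rng):
        drugs = [f"d{i:02d}" for i in range(40)]
        scores = rng.normal(size=40)
        rankings = {"disX": list(zip(drugs, scores))}
        std = standard_from({(d, "disX") for d in rng.choice(drugs, 10, replace=False)},
                            drugs)
        p = permutation_pvalue(rankings, std, metric="auc", n_perm=400, rng_seed=1)
        assert 0.1 < p.empirical < 0.95

    def test_strong_signal_floors_empirical_p(self, default_synthetic):
        graph, truth, diseases, drugs, standard = default_synthetic
        rng = np.random.default_rng(2)
        # perfect rankings: every true drug above every decoy
        rankings = {}
        for disease in diseases:
            pos = standard.positives_for(disease)
            rankings[disease] = sorted(
                ((d, (2.0 if d in pos else 1.0) + 0.001 * rng.random()) for d in drugs),
                key=lambda kv: -kv[1])
        p = permutation_pvalue(rankings, standard, metric="auc", n_perm=1000, rng_seed=3)
        assert p.empirical == pytest.approx(1 / 1001)
        assert p.gaussian < 1e-10

    def test_empirical_never_zero_and_monotone(self, rng):
        rankings, drugs = self._rankings(rng, separated=True)
        std = standard_from({(d, "disX") for d in drugs[:4]}, drugs)
        p = permutation_pvalue(rankings, std, metric="auc", n_perm=200, rng_seed=4)
        assert p.empirical > 0.0


class TestEvaluate:
    def test_perfect_single_disease(self):
        drugs = [f"d{i}" for i in range(10)]
        rankings = {"disA": [(d, 10.0 - i) for i, d in enumerate(drugs)]}
        std = standard_from({(d, "disA") for d in drugs[:3]}, drugs)
        rep = evaluate(rankings, std)
        assert rep.avg_auc == pytest.approx(1.0)
        assert rep.avg_auc01 == pytest.approx(0.1)

    def test_average_is_unweighted_mean(self):
        d1 = [f"a{i}" for i in range(10)]
        d2 = [f"b{i}" for i in range(6)]
        rankings = {
            "disA": [(d, 10.0 - i) for i, d in enumerate(d1)],  # perfect
            "disB": [(d, 1.0) for d in d2],                      # all tied: 0.5
        }
        std = standard_from({(d1[0], "disA"), (d1[1], "disA"), (d2[0], "disB")},
                            d1 + d2)
        rep = evaluate(rankings, std)
        assert rep.avg_auc == pytest.approx((1.0 + 0.5) / 2)

    def test_disease_without_positive_excluded_with_warning(self):
        drugs = [f"d{i}" for i in range(5)]
        rankings = {"good": [(d, 5.0 - i) for i, d in enumerate(drugs)],
                    "empty": [(d, 5.0 - i) for i, d in enumerate(drugs)]}
        std = standard_from({(drugs[0], "good")}, drugs)
        with pytest.warns(UserWarning, match="empty"):
            rep = evaluate(rankings, std)
        assert set(rep.per_disease) == {"good"}

    def test_random_rankings_near_chance(self, rng):
        drugs = [f"d{i:02d}" for i in range(40)]
        rankings = {f"dis{j}": list(zip(drugs, rng.normal(size=40)))
                    for j in range(10)}
        std = standard_from({(d, f"dis{j}") for j in range(10)
                             for d in rng.choice(drugs, 8, replace=False)}, drugs)
        rep = evaluate(rankings, std)
        # AUC SE per disease ~ sqrt(1/12 * (1/8 + 1/32)) ~ 0.11; mean of 10
        assert abs(rep.avg_auc - 0.5) < 3 * 0.11 / np.sqrt(10)
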