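import numpy as np
import pandas as pd
import pytest

from mnbdr import (
    ModuleSet,
    Signature,
    drug_disease_score,
    ks_connectivity,
    make_signature,
    module_rank_no_network,
    ranked_gene_list,
    xsum_score,
    zhang_score,
)
from mnbdr.io import GeneScoreVector


def vec(mapping, cid="drug"):
    return GeneScoreVector(scores=pd.Series(mapping, dtype=float), condition_id=cid,
                           condition_kind="drug")


def ks_oracle(tags, ranked):
    """Brute-force evaluation of the two max-expressions."""
    n, t = len(ranked), len(tags)
    v = sorted(ranked.index(g) + 1 for g in tags)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


class TestKSConnectivity:
    def test_extreme_concordance_and_antisymmetry(self):
        ranked = [f"g{i}" for i in range(20)]
        sig = Signature(up=("g0", "g1", "g2"), down=("g17", "g18", "g19"))
        top = ks_connectivity(sig, ranked)
        flipped = ks_connectivity(Signature(up=sig.down, down=sig.up), ranked)
        assert top > 0
        assert flipped == pytest.approx(-top)
        # no signature placement beats tags at the exact extremes
        rng = np.random.default_rng(5)
        for _ in range(30):
            genes = list(rng.permutation(ranked))
            s = Signature(up=tuple(genes[:3]), down=tuple(genes[3:6]))
            assert ks_connectivity(s, ranked) <= top + 1e-12

    def test_missing_gene_reported(self):
        with pytest.raises(ValueError, match="missing"):
            ks_connectivity(Signature(up=("nope",), down=()), ["g0", "g1"])

    def test_matches_brute_force_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        for _ in range(100):
            ranked = list(rng.permutation(genes))
            up = tuple(rng.choice(genes, size=6, replace=False))
            down = tuple(g for g in rng.choice(genes, size=6, replace=False)
                         if g not in up)
            sig = Signature(up=up, down=down)
            expected = ks_oracle(up, ranked) - (ks_oracle(down, ranked) if down else 0)
            assert ks_connectivity(sig, ranked) == pytest.approx(expected)


class TestZhangScore:
    def test_perfect_concordance_is_one(self):
        d = vec({"g0": 5.0, "g1": -4.5, "g2": 4.0, "g3": 1.0, "g4": -0.5, "g5": 0.1})
        sig = Signature(up=("g0", "g2"), down=("g1",))
        assert zhang_score(sig, d) == pytest.approx(1.0)

    def test_flipped_signs_give_minus_one(self):
        d = vec({"g0": 5.0, "g1": -4.5, "g2": 4.0, "g3": 1.0, "g4": -0.5, "g5": 0.1})
        sig = Signature(up=("g1",), down=("g0", "g2"))
        assert zhang_score(sig, d) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        genes = [f"g{i}" for i in range(40)]
        for _ in range(100):
            values = dict(zip(genes, rng.normal(size=40)))
            d = vec(values)
            up = tuple(rng.choice(genes, size=5, replace=False))
            down = tuple(g for g in rng.choice(genes, size=5, replace=False)
                         if g not in up)
            sig = Signature(up=up, down=down)
            order = sorted(genes, key=lambda g: (abs(values[g]), g))
            mag = {g: i + 1 for i, g in enumerate(order)}
            t = len(up) + len(down)
            total = sum(np.sign(values[g]) * mag[g] for g in up)
            total -= sum(np.sign(values[g]) * mag[g] for g in down)
            expected = total / sum(range(40 - t + 1, 41))
            assert zhang_score(sig, d) == pytest.approx(expected)


class TestXSumScore:
    def test_signature_outside_extremes_scores_zero(self):
        values = {f"g{i}": float(i) for i in range(10)}
        d = vec(values)
        sig = Signature(up=("g5",), down=("g4",))  # middle genes
        assert xsum_score(sig, d, extreme_k=2) == 0.0

    def test_top_gene_retained(self):
        d = vec({"g0": 5.0, "g1": 1.0, "g2": -3.0})
        assert xsum_score(Signature(up=("g0",), down=()), d, extreme_k=1) == 5.0

    def test_negating_drug_negates_score(self, rng):
        genes = [f"g{i}" for i in range(30)]
        values = dict(zip(genes, rng.normal(size=30)))
        sig = Signature(up=tuple(genes[:4]), down=tuple(genes[4:8]))
        s1 = xsum_score(sig, vec(values), extreme_k=8)
        s2 = xsum_score(sig, vec({g: -v for g, v in values.items()}), extreme_k=8)
        assert s2 == pytest.approx(-s1)

    def test_matches_truncate_and_sum(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for _ in range(100):
            values = dict(zip(genes, rng.normal(size=30)))
            k = int(rng.integers(1, 10))
            up = tuple(rng.choice(genes, size=4, replace=False))
            down = tuple(g for g in rng.choice(genes, size=4, replace=False)
                         if g not in up)
            order = sorted(genes, key=lambda g: (-values[g], g))
            keep = set(order[:k]) | set(order[-k:])
            trunc = {g: (values[g] if g in keep else 0.0) for g in genes}
            expected = sum(trunc[g] for g in up) - sum(trunc[g] for g in down)
            got = xsum_score(Signature(up=up, down=down), vec(values), extreme_k=k)
            assert got == pytest.approx(expected)


class TestSignatureAndModuleBaseline:
    def test_make_signature_sides_and_size(self, rng):
        genes = [f"g{i}" for i in range(50)]
        values = dict(zip(genes, rng.normal(size=50)))
        sig = make_signature(vec(values), k=10)
        assert len(sig.up) == 10 and len(sig.down) == 10
        assert all(values[g] > 0 for g in sig.up)
        assert all(values[g] < 0 for g in sig.down)
        assert min(values[g] for g in sig.up) >= max(
            v for g, v in values.items() if v > 0 and g not in sig.up)

    def test_ranked_gene_list_descending(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=20))}
        ranked = ranked_gene_list(vec(values))
        assert all(values[a] >= values[b] for a, b in zip(ranked, ranked[1:]))

    def test_module_baseline_agrees_with_scoring_path(self, rng):
        genes = [f"g{i}" for i in range(40)]
        ms = ModuleSet({f"M{i}": frozenset(genes[5 * i:5 * i + 5]) for i in range(8)})
        disease = vec(dict(zip(genes, rng.normal(size=40))), "dis")
        top = module_rank_no_network(disease, ms, top_n=3)
        from mnbdr.importance import module_importance
        drug_vec = vec(dict(zip(genes, rng.normal(size=40))), "drg")
        d_imp = module_importance(drug_vec, ms)
        # single disease, single drug: S computed identically given the same order
        s1 = drug_disease_score(top, d_imp).s
        s2 = drug_disease_score([m for m, _ in top], d_imp).s
        assert s1 == pytest.approx(s2)
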