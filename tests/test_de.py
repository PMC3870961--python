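"""FPKM, dispersion estimation, the conditional exact NB test and BH control."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from flylinkage.de import (
    bh_fdr,
    co_regulated_sets,
    estimate_common_dispersion,
    fpkm,
    fpkm_matrix,
    nb_exact_test,
    replicate_concordance,
)
from flylinkage.simulate import CountMatrix


def _cm(cols: dict, lengths, depth=1e5):
    gid = [f"g{i}" for i in range(len(next(iter(cols.values()))))]
    return CountMatrix(
        pd.DataFrame(cols, index=gid),
        pd.Series(np.asarray(lengths, float), index=gid),
        pd.Series(float(depth), index=list(cols)),
    )


class TestFpkm:
    def test_direct_formula(self):
        assert fpkm(100, 1000, 1_000_000) == pytest.approx(100.0)
        assert fpkm(0, 1000, 1_000_000) == 0.0

    def test_scale_invariance(self):
        assert fpkm(100, 1000, 1e6) == pytest.approx(fpkm(200, 1000, 2e6))

    def test_zero_length_or_library_rejected(self):
        with pytest.raises(ValueError):
            fpkm(10, 0, 1e6)
        with pytest.raises(ValueError):
            fpkm(10, 1000, 0)

    def test_matrix_broadcasting(self):
        cm = _cm({"s1": [100, 50], "s2": [200, 100]}, [1000, 500], depth=1e6)
        f = fpkm_matrix(cm)
        assert f.at["g0", "s1"] == pytest.approx(100.0)
        assert f.at["g1", "s2"] == pytest.approx(200.0)


class TestDispersion:
    GROUPS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def _simulated(self, phi, seed, n_genes=2000, depth=1e5):
        rng = np.random.default_rng(seed)
        base = rng.uniform(2, 8, n_genes)
        lengths = rng.integers(500, 3001, n_genes).astype(float)
        w = 2.0**base * lengths
        mu = depth * w / w.sum()
        cols = {}
        for s in self.GROUPS:
            if phi > 0:
                r = 1 / phi
                cols[s] = rng.negative_binomial(r, r / (r + mu))
            else:
                cols[s] = rng.poisson(mu)
        return _cm(cols, lengths, depth)

    def test_poisson_counts_give_near_zero(self):
        cm = self._simulated(0.0, seed=1)
        assert estimate_common_dispersion(cm, self.GROUPS) <= 0.02

    def test_nb_dispersion_recovered(self):
        cm = self._simulated(0.1, seed=2)
        assert 0.05 <= estimate_common_dispersion(cm, self.GROUPS) <= 0.2

    def test_constant_counts_give_zero(self):
        cm = _cm({s: [7, 13, 50] for s in self.GROUPS}, [1000] * 3)
        assert estimate_common_dispersion(cm, self.GROUPS) == 0.0

    def test_singleton_groups_rejected(self):
        cm = _cm({"a1": [5], "b1": [5]}, [1000])
        with pytest.raises(ValueError):
            estimate_common_dispersion(cm, {"a1": "A", "b1": "B"})


def _oracle_nb_exact(a_sum, b_sum, n_a, n_b, phi):
    """Independent brute-force conditional test via explicit log-gamma pmfs."""
    total = a_sum + b_sum

    def log_nb(k, r, mu):
        return (
            math.lgamma(k + r)
            - math.lgamma(r)
            - math.lgamma(k + 1)
            + r * math.log(r / (r + mu))
            + (k * math.log(mu / (r + mu)) if k else 0.0)
        )

    def log_pois(k, mu):
        return k * math.log(mu) - mu - math.lgamma(k + 1)

    mu = total / (n_a + n_b)
    logw = []
    for k in range(total + 1):
        if phi == 0:
            lw = log_pois(k, n_a * mu) + log_pois(total - k, n_b * mu)
        else:
            lw = log_nb(k, n_a / phi, n_a * mu) + log_nb(total - k, n_b / phi, n_b * mu)
        logw.append(lw)
    w = np.exp(np.array(logw) - max(logw))
    w /= w.sum()
    return float(w[w <= w[a_sum] * (1 + 1e-12)].sum())


class TestNbExact:
    def test_balanced_split_is_one(self):
        assert nb_exact_test([5, 5], [5, 5], 0.1) == 1.0
        assert nb_exact_test([10], [10], 0.0) == 1.0

    def test_total_zero_is_one(self):
        assert nb_exact_test([0, 0], [0, 0], 0.05) == 1.0

    def test_extreme_split_matches_exact_binomial(self):
        # phi=0, equal libraries, one sample per group, 10 vs 0
        p = nb_exact_test([10], [0], 0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.3])
    @pytest.mark.parametrize("split", [(14, 6), (3, 47), (25, 25), (0, 12)])
    def test_agrees_with_brute_force_enumeration(self, phi, split):
        a, b = split
        mine = nb_exact_test([a], [b], phi)
        assert mine == pytest.approx(_oracle_nb_exact(a, b, 1, 1, phi), abs=1e-12)

    def test_two_samples_per_group_against_oracle(self):
        mine = nb_exact_test([8, 6], [2, 4], 0.1)
        assert mine == pytest.approx(_oracle_nb_exact(14, 6, 2, 2, 0.1), abs=1e-12)

    def test_phi_zero_equals_conditional_binomial(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.integers(0, 40, 2)
            total = a + b
            if total == 0:
                continue
            pmf = stats.binom.pmf(np.arange(total + 1), total, 0.5)
            expected = pmf[pmf <= pmf[a] * (1 + 1e-12)].sum()
            assert nb_exact_test([a], [b], 0.0) == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_symmetric_under_group_swap(self):
        assert nb_exact_test([9, 3], [1, 2], 0.07) == pytest.approx(
            nb_exact_test([1, 2], [9, 3], 0.07), abs=1e-14
        )


class TestBH:
    def test_hand_computed_step_up(self):
        # p(3)=0.03 <= 3*0.05/4 rejects the three smallest
        flags = bh_fdr([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_none_rejected(self):
        assert not bh_fdr([1.0] * 5, alpha=0.05).any()

    def test_single_pvalue(self):
        assert bh_fdr([0.04], alpha=0.05).tolist() == [True]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], alpha=0.05)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.floats(min_value=0.01, max_value=0.2),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_rejections_monotone_in_alpha(self, pvals, a1, a2):
        lo, hi = sorted((a1, a2))
        assert bh_fdr(pvals, lo).sum() <= bh_fdr(pvals, hi).sum()


class TestCoRegulation:
    def _frame(self, up=(), down=(), universe=("a", "b", "c", "d")):
        return pd.DataFrame(
            {
                "significant": [g in up or g in down for g in universe],
                "direction": ["up" if g in up else "down" if g in down else "none" for g in universe],
            },
            index=list(universe),
        )

    def test_intersection(self):
        co_up, _ = co_regulated_sets(self._frame(up=("a", "b", "c")), self._frame(up=("b", "c", "d")))
        assert co_up == {"b", "c"}

    def test_disjoint_up_sets_empty(self):
        co_up, _ = co_regulated_sets(self._frame(up=("a",)), self._frame(up=("d",)))
        assert co_up == set()

    def test_direction_conflict_excluded(self):
        co_up, co_down = co_regulated_sets(self._frame(up=("a",)), self._frame(down=("a",)))
        assert "a" not in co_up and "a" not in co_down

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            co_regulated_sets(self._frame(), self._frame(universe=("a", "b")))


class TestConcordance:
    def test_identical_vectors(self):
        assert replicate_concordance([1, 2, 4, 8], [1, 2, 4, 8]) == pytest.approx(1.0)

    def test_constant_vector_is_missing(self):
        assert replicate_concordance([1, 1, 1], [1, 2, 3]) is None

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            replicate_concordance([1, 2], [1, 2])

    def test_independent_replicates_correlate(self, designs):
        # two independent sequencing replicates of the same scenario agree
        from flylinkage.de import fpkm_matrix
        from flylinkage.simulate import sample_architectures, simulate_counts

        specs = sample_architectures(800, seed=21)
        a = simulate_counts(specs, designs, mean_depth=1e6, dispersion=0.05, seed=22)
        b = simulate_counts(specs, designs, mean_depth=1e6, dispersion=0.05, seed=23)
        r2 = replicate_concordance(fpkm_matrix(a)["ALHF"], fpkm_matrix(b)["ALHF"])
        assert r2 > 0.9
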