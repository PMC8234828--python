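import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexscreen import (
    ExpressionMatrix,
    ScreenConfig,
    bh_adjust,
    centered_cosine,
    permutation_pvalues,
    run_seed_screen,
)
from coexscreen.screen import SIGN_NEGATIVE, SIGN_POSITIVE
from coexscreen.synthetic import generate_seed_screen_dataset

from conftest import pearson


class TestCenteredCosine:
    def test_self_similarity(self):
        assert centered_cosine(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == pytest.approx(1.0)

    def test_exact_reversal(self):
        assert centered_cosine(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # centered x=(-2,0,0,2), y=(-1,-1,1,1): dot=4, norms 2*sqrt(2) and 2
        x = np.array([2.0, 4, 4, 6])
        y = np.array([1.0, 1, 3, 3])
        assert centered_cosine(x, y) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_zero_norm_convention(self):
        assert centered_cosine(np.array([1.0, 1, 1]), np.array([1.0, 2, 3])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            centered_cosine(np.array([1.0, 2, 3]), np.array([1.0, 2]))

    def test_too_short(self):
        with pytest.raises(ValueError, match=">= 3"):
            centered_cosine(np.array([1.0, 2]), np.array([1.0, 2]))

    def test_equals_pearson_on_random_pairs(self, rng):
        for _ in range(1000):
            n = rng.integers(3, 30)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert abs(centered_cosine(x, y) - pearson(x, y)) < 1e-12

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=15),
        st.data(),
    )
    def test_property_bounded(self, xs, data):
        ys = data.draw(
            st.lists(st.floats(-1e3, 1e3), min_size=len(xs), max_size=len(xs))
        )
        t = centered_cosine(np.array(xs), np.array(ys))
        assert -1.0 <= t <= 1.0


class TestBHAdjust:
    def test_hand_computed(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        assert bh_adjust(np.array([0.5]))[0] == pytest.approx(0.5)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(np.array(bad))

    def _brute_force(self, p):
        """Step-up definition: q_i = min over p_(j) >= p_i of p_(j)*m/rank(j)."""
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        adj = [p[order[j]] * m / (j + 1) for j in range(m)]
        for i in range(m):
            rank_i = int(np.where(order == i)[0][0])
            q[i] = min(1.0, min(adj[rank_i:]))
        return q

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), self._brute_force(p), atol=1e-12)

    def test_order_preserving(self, rng):
        p = rng.uniform(1e-6, 1, size=100)
        q = bh_adjust(p)
        idx = np.argsort(p)
        assert np.all(np.diff(q[idx]) >= -1e-15)


def _screen_matrix(rng, n_genes=20, n_samples=8):
    values = rng.normal(size=(n_genes, n_samples))
    return ExpressionMatrix(
        [f"G{i}" for i in range(n_genes)], [f"S{j}" for j in range(n_samples)], values
    )


class TestPermutationPvalues:
    def test_add_one_floor(self, rng):
        # gene identical to the seed: no random permutation matches |T|=1
        values = rng.normal(size=(5, 10))
        values[1] = values[0]
        m = ExpressionMatrix([f"G{i}" for i in range(5)], [f"S{j}" for j in range(10)], values)
        cfg = ScreenConfig("G0", n_permutations=1000, rng_seed=3, exhaustive=False)
        _, p = permutation_pvalues(m, cfg)
        assert p[1] == pytest.approx(1 / 1001)

    def test_zero_variance_gene(self, rng):
        values = rng.normal(size=(3, 8))
        values[2] = 4.2
        m = ExpressionMatrix(["G0", "G1", "G2"], [f"S{j}" for j in range(8)], values)
        t, p = permutation_pvalues(m, ScreenConfig("G0", rng_seed=0, exhaustive=False))
        assert t[2] == 0.0
        assert p[2] == 1.0

    def test_seed_absent(self, rng):
        m = _screen_matrix(rng)
        with pytest.raises(KeyError, match="NOPE"):
            permutation_pvalues(m, ScreenConfig("NOPE"))

    def test_too_few_samples(self, rng):
        m = _screen_matrix(rng, n_samples=3)
        with pytest.raises(ValueError, match=">= 4"):
            permutation_pvalues(m, ScreenConfig("G0"))

    def test_monte_carlo_close_to_exhaustive_oracle(self, rng):
        """Independent enumeration of all 120 orderings at n=5."""
        m = _screen_matrix(rng, n_genes=25, n_samples=5)
        cfg_mc = ScreenConfig("G0", n_permutations=1000, rng_seed=11, exhaustive=False)
        t_obs, p_mc = permutation_pvalues(m, cfg_mc)
        seed_profile = m.values[0]
        for i in range(m.n_genes):
            gene = m.values[i]
            t0 = abs(pearson(gene, seed_profile))
            count = sum(
                1
                for perm in itertools.permutations(range(5))
                if abs(pearson(gene, seed_profile[list(perm)])) >= t0 - 1e-12
            )
            p_ex = count / 120
            se = np.sqrt(p_ex * (1 - p_ex) / 1000)
            assert abs(p_mc[i] - p_ex) <= 3 * se + 2 / 1001

    def test_exhaustive_mode_matches_oracle_exactly(self, rng):
        m = _screen_matrix(rng, n_genes=10, n_samples=5)
        t_obs, p = permutation_pvalues(m, ScreenConfig("G0", exhaustive=True))
        seed_profile = m.values[0]
        for i in range(m.n_genes):
            t0 = abs(pearson(m.values[i], seed_profile))
            count = sum(
                1
                for perm in itertools.permutations(range(5))
                if abs(pearson(m.values[i], seed_profile[list(perm)])) >= t0 - 1e-12
            )
            assert p[i] == pytest.approx(count / 120, abs=1e-12)

    def test_relabelling_symmetry_exhaustive(self, rng):
        # a common re-ordering of all samples leaves exhaustive p unchanged
        m = _screen_matrix(rng, n_genes=8, n_samples=5)
        cfg = ScreenConfig("G0", exhaustive=True)
        _, p1 = permutation_pvalues(m, cfg)
        sigma = rng.permutation(5)
        m2 = ExpressionMatrix(
            m.gene_ids, [m.sample_ids[j] for j in sigma], m.values[:, sigma]
        )
        _, p2 = permutation_pvalues(m2, cfg)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        matrix, _ = generate_seed_screen_dataset(500, 0, 0, 10, 0.5, 1.0, rng_seed=5)
        cfg = ScreenConfig("GENE_SEED", n_permutations=1000, rng_seed=6, exhaustive=False)
        _, p = permutation_pvalues(matrix, cfg)
        p = p[1:]  # drop the seed gene itself
        assert kstest(p, "uniform").statistic < 0.07


class TestRunSeedScreen:
    def test_seed_gene_excluded(self, rng):
        m = _screen_matrix(rng, n_genes=12, n_samples=8)
        res = run_seed_screen(m, ScreenConfig("G0", rng_seed=1, exhaustive=False))
        assert "G0" not in set(res.table["gene_id"])
        assert len(res.table) == 11

    def test_planted_signs_recovered(self):
        matrix, truth = generate_seed_screen_dataset(
            1000, 50, 50, 20, planted_r=0.9, rng_seed=42
        )
        res = run_seed_screen(
            matrix, ScreenConfig("GENE_SEED", rng_seed=43, exhaustive=False)
        )
        sig = res.table[res.table["sign"] != "nonsignificant"]
        planted_pos = set(truth.pos_module)
        planted_neg = set(truth.neg_module)
        for _, row in sig.iterrows():
            if row["gene_id"] in planted_pos:
                assert row["sign"] == SIGN_POSITIVE
            if row["gene_id"] in planted_neg:
                assert row["sign"] == SIGN_NEGATIVE
        # the screen should find most of the strongly planted genes
        found = set(sig["gene_id"])
        assert len(found & planted_pos) >= 45
        assert len(found & planted_neg) >= 45

    def test_null_config_fdr_controlled(self):
        # pure-null data: false-positive proportion under the threshold on average
        total_sig = 0
        total_genes = 0
        for seed in range(20):
            matrix, _ = generate_seed_screen_dataset(200, 0, 0, 12, 0.5, 1.0, rng_seed=seed)
            res = run_seed_screen(
                matrix,
                ScreenConfig("GENE_SEED", n_permutations=500, rng_seed=seed + 100, exhaustive=False),
            )
            total_sig += res.n_positive + res.n_negative
            total_genes += len(res.table)
        assert total_sig / total_genes <= 0.1

    def test_sorted_by_q_then_abs_similarity(self, rng):
        m = _screen_matrix(rng, n_genes=30, n_samples=8)
        res = run_seed_screen(m, ScreenConfig("G0", rng_seed=2, exhaustive=False))
        q = res.table["q_value"].to_numpy()
        assert np.all(np.diff(q) >= -1e-15)

    def test_monotonic_in_planted_r(self):
        medians = []
        for r in (0.2, 0.5, 0.8):
            matrix, truth = generate_seed_screen_dataset(50, 40, 0, 30, r, rng_seed=7)
            res = run_seed_screen(
                matrix, ScreenConfig("GENE_SEED", rng_seed=8, exhaustive=False)
            )
            planted = res.table[res.table["gene_id"].isin(truth.pos_module)]
            medians.append(planted["similarity"].abs().median())
        assert medians[0] <= medians[1] <= medians[2]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_permutations"):
            ScreenConfig("G0", n_permutations=10)
        with pytest.raises(ValueError, match="fdr_threshold"):
            ScreenConfig("G0", fdr_threshold=1.5)
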