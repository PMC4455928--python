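"""RNA-seq DE: filters, normalization, the NB exact test, BH, consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yolkde import (
    CountMatrix,
    SimConfig,
    bh_adjust,
    call_rnaseq_de,
    consistency_filter,
    filter_max_count,
    nb_exact_test,
    normalize_libsize,
    simulate_rnaseq_counts,
)


def _cm(rows, gene_ids=None):
    rows = np.atleast_2d(rows)
    counts = pd.DataFrame(
        rows,
        index=pd.Index(gene_ids or [f"g{i}" for i in range(len(rows))],
                       name="gene_id"),
        columns=["YD_b1", "SP_b1", "YD_b2", "SP_b2", "YD_b3", "SP_b3"],
    )
    meta = pd.DataFrame(
        {"condition": ["YD", "SP"] * 3,
         "batch": ["b1", "b1", "b2", "b2", "b3", "b3"]},
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts, meta)


class TestFilterMaxCount:
    def test_boundary_gene_at_threshold_is_dropped(self):
        cm = _cm([[0, 1, 5, 2, 0, 3], [6, 0, 0, 0, 0, 0]])
        kept = filter_max_count(cm, 5)
        assert list(kept.gene_ids) == ["g1"]

    def test_counts_match_brute_force_row_scan(self):
        rng = np.random.default_rng(0)
        rows = rng.poisson(4, size=(100, 6))
        cm = _cm(rows)
        kept = filter_max_count(cm, 5)
        expected = sum(1 for r in rows if r.max() > 5)
        assert kept.n_genes == expected
        # order preserved
        assert list(kept.gene_ids) == [g for g, r in zip(cm.gene_ids, rows)
                                       if r.max() > 5]


class TestNormalizeLibsize:
    def test_identical_samples_get_unit_factors(self, tiny_counts):
        doubled = CountMatrix(
            pd.concat([tiny_counts.counts.iloc[:, :1]] * 6, axis=1)
            .set_axis(tiny_counts.counts.columns, axis=1),
            tiny_counts.sample_meta,
        )
        np.testing.assert_allclose(normalize_libsize(doubled), 1.0)

    def test_doubled_sample_gives_sqrt2_split(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=(30, 1))
        rows = np.hstack([base, 2 * base, base, 2 * base, base, 2 * base])
        factors = normalize_libsize(_cm(rows))
        np.testing.assert_allclose(
            factors.to_numpy(),
            [1 / np.sqrt(2), np.sqrt(2)] * 3,
            rtol=1e-12,
        )

    def test_geometric_mean_is_one(self, tiny_counts):
        factors = normalize_libsize(tiny_counts)
        assert np.exp(np.log(factors).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_reference_errors(self):
        with pytest.raises(ValueError):
            normalize_libsize(_cm([[0, 1, 0, 2, 0, 3], [1, 0, 2, 0, 3, 0]]))


class TestNbExactTest:
    def test_symmetric_group_totals_give_p_one(self):
        cm = _cm([[5, 5, 5, 5, 5, 5]])
        res = nb_exact_test(cm, normalize_libsize(cm))
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)
        assert res["score"].iloc[0] == pytest.approx(0.0)

    def test_all_zero_gene_gets_p_one_effect_zero(self):
        cm = _cm([[0, 0, 0, 0, 0, 0], [9, 5, 8, 6, 7, 5]])
        res = nb_exact_test(cm, pd.Series(1.0, index=cm.counts.columns))
        assert res.loc["g0", "p_raw"] == 1.0
        assert res.loc["g0", "score"] == 0.0

    def test_null_calibration_monte_carlo(self):
        """Fraction of raw p < 0.05 stays near nominal over 5 null seeds."""
        fracs = []
        for seed in range(5):
            cm, _ = simulate_rnaseq_counts(SimConfig(n_genes=2000, seed=seed))
            res = nb_exact_test(cm, normalize_libsize(cm))
            fracs.append((res["p_raw"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_strong_spikes_reach_tiny_p(self):
        cfg = SimConfig(n_genes=1000, n_spiked=50, spike_log2fc=3.0, seed=1)
        cm, truth = simulate_rnaseq_counts(cfg)
        res = nb_exact_test(cm, normalize_libsize(cm))
        spiked_p = res.loc[truth["gene_id"], "p_raw"]
        assert np.median(spiked_p) < 1e-3


class TestBhAdjust:
    def test_hand_calculated_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])
        assert bh_adjust([]).size == 0

    def test_matches_brute_force_oracle_on_random_vectors(self):
        def brute_force(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            for rank_pos, i in enumerate(order):
                j = rank_pos + 1
                adj[i] = min(
                    min(p[order[k]] * m / (k + 1) for k in range(rank_pos, m)),
                    1.0,
                )
            return adj

        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), brute_force(p), atol=1e-12)

    def test_matches_statsmodels_on_large_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(500)
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestConsistencyFilter:
    def _candidates(self, cm, passed=True):
        return pd.DataFrame({
            "gene_id": cm.gene_ids, "score": 1.0, "p_raw": 0.001,
            "fdr": 0.01, "direction": "up_in_YD", "passed": passed,
        })

    def test_same_sign_in_all_batches_is_kept(self):
        cm = _cm([[13, 10, 11, 10, 17, 10]])  # diffs +3.1-ish, +1, +7
        out = consistency_filter(cm, self._candidates(cm),
                                 pd.Series(1.0, index=cm.counts.columns))
        assert bool(out["passed"].iloc[0])

    def test_sign_flip_in_one_batch_is_dropped(self):
        cm = _cm([[13, 10, 9, 10, 17, 10]])
        out = consistency_filter(cm, self._candidates(cm),
                                 pd.Series(1.0, index=cm.counts.columns))
        assert not bool(out["passed"].iloc[0])

    def test_zero_difference_counts_as_inconsistent(self):
        cm = _cm([[13, 10, 10, 10, 17, 10]])
        out = consistency_filter(cm, self._candidates(cm),
                                 pd.Series(1.0, index=cm.counts.columns))
        assert not bool(out["passed"].iloc[0])

    def test_never_promotes_a_gene(self):
        cm = _cm([[13, 10, 11, 10, 17, 10]])
        out = consistency_filter(cm, self._candidates(cm, passed=False),
                                 pd.Series(1.0, index=cm.counts.columns))
        assert not out["passed"].any()


class TestCallRnaseqDe:
    def test_null_simulation_passes_almost_nothing(self):
        """FDR control: at most 2 called genes in >= 9 of 10 null seeds."""
        quiet = 0
        for seed in range(10):
            cm, _ = simulate_rnaseq_counts(SimConfig(n_genes=2000, seed=seed))
            de = call_rnaseq_de(cm)
            quiet += int(de["passed"].sum()) <= 2
        assert quiet >= 9

    def test_strong_spikes_recovered_with_direction(self):
        cfg = SimConfig(n_genes=2000, n_spiked=100, spike_log2fc=3.0, seed=1)
        cm, truth = simulate_rnaseq_counts(cfg)
        de = call_rnaseq_de(cm)
        merged = de[de["passed"]].merge(truth, on="gene_id",
                                        suffixes=("", "_truth"))
        assert len(merged) >= 80
        assert (merged["direction"] == merged["direction_truth"]).all()
        # empirical FDR among calls stays below twice the nominal level
        n_called = int(de["passed"].sum())
        assert (n_called - len(merged)) <= max(2, 0.1 * n_called)

    def test_directions_partition_passed_genes(self, small_config):
        cm, _ = simulate_rnaseq_counts(small_config)
        de = call_rnaseq_de(cm)
        passed = de[de["passed"]]
        up = set(passed.loc[passed["direction"] == "up_in_YD", "gene_id"])
        down = set(passed.loc[passed["direction"] == "down_in_YD", "gene_id"])
        assert not up & down
        assert up | down == set(passed["gene_id"])
        assert (passed["fdr"] < 0.05).all()
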