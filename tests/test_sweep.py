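"""Windowed FST, Z-transform, pi-ratio, outlier intersection, gene mapping
and enrichment testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import comb

import admixscan as ax
from admixscan.sweep import wc_site_components

from conftest import make_gm
from oracles import naive_bh, naive_top_intersection


def _popmap(gm, n_a):
    return ax.PopulationMap(
        pd.DataFrame(
            {
                "sample": gm.sample_ids,
                "population": ["A"] * n_a + ["B"] * (gm.n_samples - n_a),
            }
        )
    )


class TestWindowedFst:
    def test_fixed_difference_is_one(self):
        G = np.vstack([np.zeros((10, 20)), np.full((10, 20), 2)]).astype(np.int8)
        gm = make_gm(G, chrom_lengths={"chr1": 20_000})
        pm = _popmap(gm, 10)
        out = ax.windowed_fst(gm, pm, "A", "B", window=20_000, step=20_000)
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_null_split_near_zero(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.05, 0.95, 5000)
        G = rng.binomial(2, f, size=(200, 5000)).astype(np.int8)
        gm = make_gm(G, chrom_lengths={"chr1": 5_000_000})
        pm = _popmap(gm, 100)
        assert abs(ax.genome_mean_fst(gm, pm, "A", "B")) <= 0.01

    def test_estimator_tracks_simulation_divergence(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 8000)
        f1, f2 = ax.simulate_ancestral_freqs(p, 0.10, rng)
        G = np.vstack(
            [
                rng.binomial(2, f1, size=(80, 8000)),
                rng.binomial(2, f2, size=(80, 8000)),
            ]
        ).astype(np.int8)
        gm = make_gm(G, chrom_lengths={"chr1": 8_000_000})
        fst = ax.genome_mean_fst(gm, _popmap(gm, 80), "A", "B")
        assert 0.08 <= fst <= 0.12

    def test_sites_need_two_called_per_population(self):
        G = np.array([[0, 0], [-1, 2], [2, 2], [2, 2]], dtype=np.int8)
        a, b, c, valid = wc_site_components(G, np.array([0, 1]), np.array([2, 3]))
        assert list(valid) == [False, True]

    def test_unknown_population_error(self):
        gm = make_gm(np.zeros((4, 2), dtype=np.int8))
        pm = _popmap(gm, 2)
        with pytest.raises(KeyError):
            ax.windowed_fst(gm, pm, "A", "Z")


class TestZTransform:
    def test_hand_example(self):
        np.testing.assert_allclose(
            ax.z_transform([0.1, 0.2, 0.3]), [-1.0, 0.0, 1.0], atol=1e-12
        )

    def test_constant_vector_error(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            ax.z_transform([0.5, 0.5, 0.5])

    def test_moments_and_missing_passthrough(self):
        x = np.array([0.1, np.nan, 0.4, 0.2, 0.9])
        z = ax.z_transform(x)
        assert np.isnan(z[1])
        ok = np.isfinite(z)
        assert z[ok].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[ok].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=3, max_size=40
        ).filter(lambda v: np.std(v, ddof=1) > 1e-6)
    )
    def test_idempotent_on_standardized_input(self, values):
        z = ax.z_transform(values)
        np.testing.assert_allclose(ax.z_transform(z), z, atol=1e-9)


class TestLog2Ratio:
    def test_hand_examples(self):
        out = ax.log2_pi_ratio([0.002, 0.001], [0.001, 0.001])
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_zero_pi_excluded(self):
        out = ax.log2_pi_ratio([0.002, 0.001], [0.0, 0.001])
        assert np.isnan(out[0]) and out[1] == 0.0


class TestSelectOutliers:
    def _table(self, z, r):
        return pd.DataFrame(
            {"chrom": "chr1", "start": 1, "end": 2, "z_fst": z,
             "log2_ratio": r}
        )

    def test_matches_double_ranking_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(100)
        r = rng.standard_normal(100)
        out, _, _ = ax.select_outliers(self._table(z, r), 0.05)
        assert set(np.flatnonzero(out["outlier"])) == \
            naive_top_intersection(z, r, 0.05)

    def test_rank_correlated_statistics(self):
        z = np.arange(100, dtype=float)
        out, _, _ = ax.select_outliers(self._table(z, z * 2), 0.05)
        assert out["outlier"].sum() == 5
        assert set(np.flatnonzero(out["outlier"])) == set(range(95, 100))

    def test_top_fraction_one_flags_all_retained(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(30)
        r = rng.standard_normal(30)
        r[0] = np.nan
        out, _, _ = ax.select_outliers(self._table(z, r), 1.0)
        assert out["outlier"].sum() == 29

    def test_nan_windows_never_flagged(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(50)
        r = rng.standard_normal(50)
        z[:10] = np.nan
        out, _, _ = ax.select_outliers(self._table(z, r), 0.1)
        assert not out["outlier"][:10].any()


class TestSweepScanAndGenes:
    def _scan(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 2000)
        f1, f2 = ax.simulate_ancestral_freqs(p, 0.05, rng)
        G = np.vstack(
            [
                rng.binomial(2, f1, size=(40, 2000)),
                rng.binomial(2, f2, size=(40, 2000)),
            ]
        ).astype(np.int8)
        gm = make_gm(G, chrom_lengths={"chr1": 2_000_000})
        # implant a sweep in pop B at 0.9–1.1 Mb
        gm = ax.implant_sweep(
            gm, f2, ("chr1", 900_001, 1_100_000), gm.sample_ids[40:],
            np.random.default_rng(6),
        )
        return gm, _popmap(gm, 40)

    def test_sweep_region_flagged(self):
        gm, pm = self._scan()
        cand = ax.sweep_scan(gm, pm, "A", "B", window=50_000, step=10_000)
        out = cand.windows
        hits = out[out["outlier"]]
        assert len(hits) > 0
        overlap = (hits["start"] <= 1_100_000) & (hits["end"] >= 900_001)
        assert overlap.any()

    def test_gene_mapping_and_dedup(self):
        gm, pm = self._scan()
        cand = ax.sweep_scan(gm, pm, "A", "B", window=50_000, step=10_000)
        ann = ax.simulate_gene_annotation({"chr1": 2_000_000}, 2000, 8000)
        cand = ax.map_windows_to_genes(cand, ann, gm)
        assert len(cand.genes) == len(set(cand.genes))
        # every SNP lies in some outlier window
        hits = cand.windows[cand.windows["outlier"]]
        for pos in cand.snps["pos"]:
            assert ((hits["start"] <= pos) & (pos <= hits["end"])).any()

    def test_gene_overlap_by_one_bp(self):
        win = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1], "end": [50_000],
             "outlier": [True]}
        )
        ann = ax.GeneAnnotation(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [9_999, 50_000],
                 "end": [12_000, 52_000], "name": ["in", "out"],
                 "strand": ["+", "+"]}
            )
        )
        gm = make_gm(np.zeros((2, 3), dtype=np.int8))
        cand = ax.CandidateSet(windows=win)
        cand = ax.map_windows_to_genes(cand, ann, gm)
        assert cand.genes == ["in"]

    def test_no_outliers_empty_genes(self):
        win = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1], "end": [50_000],
             "outlier": [False]}
        )
        ann = ax.simulate_gene_annotation({"chr1": 100_000}, 2000, 8000)
        gm = make_gm(np.zeros((2, 3), dtype=np.int8))
        cand = ax.map_windows_to_genes(ax.CandidateSet(windows=win), ann, gm)
        assert cand.genes == []


class TestEnrichment:
    def test_closed_form_all_overlap(self):
        # N=20, K=5, n=5, x=5 -> p = 1/C(20,5)
        bg = [f"g{i}" for i in range(20)]
        cand = bg[:5]
        res = ax.enrichment(cand, bg, {"T": bg[:5]})
        assert res["p_value"].iloc[0] == pytest.approx(
            1.0 / comb(20, 5, exact=True), rel=1e-12
        )

    def test_zero_overlap_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        res = ax.enrichment(bg[:5], bg, {"T": bg[5:10]})
        assert res["p_value"].iloc[0] <= 1.0
        res0 = ax.enrichment(bg[:1], bg, {"T": bg[10:]})
        # x = 0: P(X >= 0) = 1
        assert res0["p_value"].iloc[0] == pytest.approx(1.0)

    def test_fisher_agrees_with_hypergeometric(self):
        rng = np.random.default_rng(7)
        bg = [f"g{i}" for i in range(50)]
        cand = list(rng.choice(bg, size=12, replace=False))
        terms = {
            f"T{k}": list(rng.choice(bg, size=rng.integers(3, 20),
                                     replace=False))
            for k in range(8)
        }
        hyper = ax.enrichment(cand, bg, terms, method="hypergeometric")
        fisher = ax.enrichment(cand, bg, terms, method="fisher")
        merged = hyper.merge(fisher, on="term", suffixes=("_h", "_f"))
        np.testing.assert_allclose(
            merged["p_value_h"], merged["p_value_f"], atol=1e-12
        )

    def test_bh_step_up_hand_values(self):
        bg = [f"g{i}" for i in range(30)]
        # craft three terms; check BH against the naive step-up oracle
        rng = np.random.default_rng(8)
        cand = list(rng.choice(bg, size=10, replace=False))
        terms = {f"T{k}": list(rng.choice(bg, size=6, replace=False))
                 for k in range(5)}
        res = ax.enrichment(cand, bg, terms)
        np.testing.assert_allclose(
            res["q_value"], naive_bh(res["p_value"]), atol=1e-12
        )
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()

    def test_bh_arithmetic_example(self):
        np.testing.assert_allclose(
            naive_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_candidates_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            ax.enrichment(["x"], ["a", "b"], {"T": ["a"]})

    def test_empty_term_skipped(self):
        bg = ["a", "b", "c"]
        res = ax.enrichment(["a"], bg, {"T1": ["zzz"], "T2": ["a", "b"]})
        assert list(res["term"]) == ["T2"]
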