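"""Diversity indices, windowed pi, locus filters and dataset merging,
checked against closed forms and naive recount oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import admixscan as ax
from admixscan.diversity import per_site_pi, window_grid

from conftest import make_gm, random_gm
from oracles import naive_filter, naive_locus_stats, naive_site_pi


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ([0, 1, 2], 0.5),
            ([2, 2, 2, 2], 1.0),
            ([0, 1, -1, 2], 0.5),  # missing dropped
        ],
    )
    def test_hand_examples(self, col, expected):
        gm = make_gm(np.array(col)[:, None])
        assert ax.allele_frequency(gm)[0] == pytest.approx(expected)

    def test_all_missing_locus_flagged(self):
        gm = make_gm(np.array([[-1], [-1]]))
        st_ = ax.locus_stats(gm)
        assert not st_["defined"].iloc[0]
        assert np.isnan(st_["p_alt"].iloc[0])


class TestLocusDiversity:
    def test_closed_forms_p_half(self):
        # p = 0.5: He = Nei = PIC(gene-diversity form) = 0.5, Botstein PIC = 0.375
        gm = make_gm(np.array([[0], [2]]))
        gd = ax.locus_stats(gm, pic_variant="nei")
        bot = ax.locus_stats(gm, pic_variant="botstein")
        assert gd["he"].iloc[0] == pytest.approx(0.5)
        assert gd["nei"].iloc[0] == pytest.approx(0.5)
        assert gd["pic"].iloc[0] == pytest.approx(0.5)
        assert bot["pic"].iloc[0] == pytest.approx(0.375)

    def test_observed_heterozygosity(self):
        gm = make_gm(np.array([[0], [1], [1], [2]]))
        assert ax.locus_stats(gm)["ho"].iloc[0] == pytest.approx(0.5)

    def test_p_point_one(self):
        gm = make_gm(np.array([[1]] + [[0]] * 4))  # p = 0.1
        st_ = ax.locus_stats(gm)
        assert st_["he"].iloc[0] == pytest.approx(0.18)
        assert st_["maf"].iloc[0] == pytest.approx(0.1)

    def test_monomorphic_locus_all_zero_stats(self):
        gm = make_gm(np.zeros((5, 1), dtype=np.int8))
        st_ = ax.locus_stats(gm)
        assert st_[["ho", "he", "nei", "pic", "maf"]].iloc[0].eq(0).all()

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            gm = random_gm(rng)
            for variant in ("nei", "botstein"):
                st_ = ax.locus_stats(gm, pic_variant=variant)
                for j in range(gm.n_loci):
                    expect = naive_locus_stats(gm.G[:, j].tolist(), variant)
                    if expect is None:
                        assert not st_["defined"].iloc[j]
                        continue
                    for key, val in expect.items():
                        assert st_[key].iloc[j] == pytest.approx(
                            val, abs=1e-12
                        ), (variant, key, j)

    def test_biallelic_identities(self):
        # nei == he and botstein PIC <= gene-diversity PIC <= he at every locus
        rng = np.random.default_rng(3)
        gm = random_gm(rng, n=30, m=80)
        gd = ax.locus_stats(gm, pic_variant="nei")
        bot = ax.locus_stats(gm, pic_variant="botstein")
        ok = gd["defined"]
        assert np.allclose(gd.loc[ok, "nei"], gd.loc[ok, "he"])
        assert (bot.loc[ok, "pic"] <= gd.loc[ok, "pic"] + 1e-12).all()
        assert (gd.loc[ok, "pic"] <= gd.loc[ok, "he"] + 1e-12).all()


class TestPopulationSummary:
    def test_mean_of_two_loci(self):
        # he 0.2 (p=...) and 0.4 -> mean 0.3; build via explicit frequencies
        G = np.array([[1, 1], [0, 1], [0, 1], [0, 1], [0, 0]] * 2)
        gm = make_gm(G)
        pm = ax.PopulationMap.from_dict({s: "P" for s in gm.sample_ids})
        st_ = ax.locus_stats(gm)
        out = ax.population_summary(gm, pm)
        assert out["he"].iloc[0] == pytest.approx(st_["he"].mean())

    def test_hwe_population_ho_matches_he(self):
        rng = np.random.default_rng(11)
        f = rng.uniform(0.05, 0.95, 10_000)
        G = rng.binomial(2, f, size=(200, 10_000)).astype(np.int8)
        gm = make_gm(G)
        pm = ax.PopulationMap.from_dict({s: "P" for s in gm.sample_ids})
        out = ax.population_summary(gm, pm)
        assert abs(out["ho"].iloc[0] - out["he"].iloc[0]) < 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        gm = random_gm(rng)
        pm = ax.PopulationMap.from_dict({s: "P" for s in gm.sample_ids})
        a = ax.population_summary(gm, pm)
        b = ax.population_summary(gm, pm)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_population_is_error(self):
        gm = make_gm(np.zeros((2, 2), dtype=np.int8))
        pm = ax.PopulationMap(
            pd.DataFrame({"sample": ["s0", "s1", "zz"],
                          "population": ["A", "A", "B"]})
        )
        with pytest.raises((ValueError, KeyError)):
            ax.population_summary(gm, pm)


class TestWindowedPi:
    def test_single_site_unbiased_formula(self):
        # genotypes [0, 2]: c_alt = 2, c_ref = 2, c = 4 -> pi = 2/3
        gm = make_gm(np.array([[0], [2]]))
        assert per_site_pi(gm)[0] == pytest.approx(2.0 / 3.0)
        assert naive_site_pi([0, 2]) == pytest.approx(2.0 / 3.0)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(21)
        gm = random_gm(rng, n=15, m=40)
        pi = per_site_pi(gm)
        for j in range(gm.n_loci):
            assert pi[j] == pytest.approx(
                naive_site_pi(gm.G[:, j].tolist()), abs=1e-12
            )

    def test_window_grid_positions(self):
        grid = window_grid({"chr1": 100_000}, 50_000, 10_000)
        assert list(grid["start"][:3]) == [1, 10_001, 20_001]
        assert grid["end"].iloc[0] == 50_000
        assert grid["end"].iloc[-1] == 100_000  # truncated terminal window

    def test_empty_window_zero(self):
        gm = make_gm(np.array([[0], [2]]), spacing=1000,
                     chrom_lengths={"chr1": 100_000})
        out = ax.windowed_pi(gm, window=10_000, step=10_000)
        assert out["pi_per_bp"].iloc[1:].eq(0).all()
        assert out["n_variant_sites"].iloc[1:].eq(0).all()
        assert out["pi_per_bp"].iloc[0] == pytest.approx((2 / 3) / 10_000)

    def test_truncated_window_uses_actual_span(self):
        gm = make_gm(np.array([[0], [2]]), spacing=1000,
                     chrom_lengths={"chr1": 1500})
        out = ax.windowed_pi(gm, window=1000, step=1000)
        # second window spans 1001..1500 (500 bp), no variants
        assert out["end"].iloc[1] == 1500
        assert out["pi_per_bp"].iloc[0] == pytest.approx((2 / 3) / 1000)

    def test_estimator_unbiased_under_hwe(self):
        rng = np.random.default_rng(31)
        p = 0.3
        G = rng.binomial(2, p, size=(200, 2000)).astype(np.int8)
        gm = make_gm(G, spacing=50, chrom_lengths={"chr1": 100_000})
        out = ax.windowed_pi(gm, window=100_000, step=100_000)
        total_pi = out["pi_per_bp"].iloc[0] * 100_000
        expected = 2 * p * (1 - p) * 2000
        assert abs(total_pi / expected - 1) < 0.02

    def test_bad_window_config(self):
        gm = make_gm(np.array([[0], [2]]))
        with pytest.raises(ValueError):
            ax.windowed_pi(gm, window=0, step=10)
        with pytest.raises(ValueError):
            ax.windowed_pi(gm, window=10, step=100)


class TestFilterLoci:
    def _toy(self):
        # 10 loci engineered to exercise every filter step
        rng = np.random.default_rng(100)
        n = 10
        G = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
        D = np.full((n, 10), 10)
        G[:, 0] = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]   # maf 0.05 -> kept
        G[:, 1] = 0                                  # maf 0 -> dropped at MAF
        G[:, 2] = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        D[:, 3] = 2                                  # all masked -> missing
        D[:4, 4] = 2                                 # 40% masked -> missing>0.3
        G[:3, 5] = -1                                # 30% missing -> kept
        G[:, 6] = [0, 2, 1, 1, 0, 2, 0, 1, 2, 0]
        D[:2, 7] = 3                                 # 20% masked, kept
        G[:, 8] = [2, 2, 2, 2, 2, 2, 2, 2, 2, 1]   # maf 0.05
        G[:, 9] = [1, -1, -1, -1, 0, 0, 0, 0, 0, 0]  # 30% missing, maf .071
        return make_gm(G, depths=D)

    def test_matches_hand_applied_oracle(self):
        gm = self._toy()
        out, report = ax.filter_loci(
            gm, min_depth=4, max_missing=0.3, min_maf=0.01,
            min_site_quality=None,
        )
        cols = [
            {"g": gm.G[:, j].tolist(), "d": gm.D[:, j].tolist()}
            for j in range(gm.n_loci)
        ]
        expected = naive_filter(cols)
        got = [int(p) // 1000 - 1 for p in out.loci["pos"]]
        assert got == expected
        assert report.loc[report["step"] == "maf", "n_out"].iloc[0] == len(expected)

    def test_maf_threshold_boundary(self):
        # MAF 0.005 dropped, 0.01 kept (threshold is >=)
        G = np.zeros((100, 2), dtype=np.int8)
        G[0, 0] = 1          # maf 0.005
        G[:2, 1] = 1         # maf 0.01
        gm = make_gm(G)
        out, _ = ax.filter_loci(gm, min_depth=None, max_missing=None,
                                min_site_quality=None, min_maf=0.01)
        assert out.n_loci == 1
        assert out.loci["pos"].iloc[0] == 2000

    def test_all_disabled_is_identity(self):
        rng = np.random.default_rng(8)
        gm = random_gm(rng)
        out, report = ax.filter_loci(
            gm, min_depth=None, max_missing=None, min_maf=None,
            min_site_quality=None,
        )
        np.testing.assert_array_equal(out.G, gm.G)
        assert len(report) == 0

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        gm = random_gm(rng, with_depth=True)
        once, _ = ax.filter_loci(gm, min_site_quality=None)
        twice, _ = ax.filter_loci(once, min_site_quality=None)
        np.testing.assert_array_equal(once.G, twice.G)
        pd.testing.assert_frame_equal(once.loci, twice.loci)

    def test_site_quality_filter(self):
        gm = make_gm(np.array([[0, 1], [1, 1]]))
        gm.loci["site_quality"] = [10.0, 30.0]
        out, _ = ax.filter_loci(gm, min_depth=None, max_missing=None,
                                min_maf=None, min_site_quality=20)
        assert out.n_loci == 1
        assert out.loci["site_quality"].iloc[0] == 30.0

    def test_depth_filter_without_depths_is_error(self):
        gm = make_gm(np.array([[0], [2]]))
        with pytest.raises(ValueError, match="depth"):
            ax.filter_loci(gm, min_depth=4, min_site_quality=None)


class TestMergeDatasets:
    def _pair(self):
        a = make_gm(np.array([[0, 1], [1, 2]]), sample_prefix="a")
        b_loci = pd.DataFrame(
            {"chrom": "chr1", "pos": [2000, 3000], "ref": "A", "alt": "C"}
        )
        b = ax.GenotypeMatrix(["b0", "b1"], b_loci, np.array([[2, 0], [0, 0]],
                                                            dtype=np.int8))
        return a, b

    def test_intersection_on_position(self):
        a, b = self._pair()
        merged = ax.merge_datasets(a, b)
        assert merged.n_loci == 1
        assert merged.loci["pos"].iloc[0] == 2000
        assert merged.sample_ids == ["a0", "a1", "b0", "b1"]
        np.testing.assert_array_equal(merged.G[:, 0], [1, 2, 2, 0])

    def test_conflicting_alleles_error(self):
        a, b = self._pair()
        b.loci.loc[0, ["ref", "alt"]] = ["C", "A"]  # swapped
        with pytest.raises(ValueError, match="conflicting alleles"):
            ax.merge_datasets(a, b)

    def test_self_merge_doubles_samples(self):
        rng = np.random.default_rng(13)
        a = random_gm(rng, n=5, m=20)
        b = a.copy()
        b.sample_ids = [f"dup_{s}" for s in b.sample_ids]
        merged = ax.merge_datasets(a, b)
        assert merged.n_samples == 10
        assert merged.n_loci == 20

    def test_duplicate_sample_ids_error(self):
        rng = np.random.default_rng(14)
        a = random_gm(rng, n=3, m=5)
        with pytest.raises(ValueError, match="duplicate sample"):
            ax.merge_datasets(a, a.copy())


@given(
    arrays(np.int8, (8, 12), elements=st.integers(min_value=-1, max_value=2))
)
def test_stats_bounded_property(G):
    """All defined diversity statistics lie in their theoretical ranges."""
    gm = make_gm(G)
    st_ = ax.locus_stats(gm)
    ok = st_["defined"]
    for col, hi in (("maf", 0.5), ("ho", 1.0), ("he", 0.5), ("pic", 0.5)):
        vals = st_.loc[ok, col]
        assert ((vals >= -1e-12) & (vals <= hi + 1e-12)).all()
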