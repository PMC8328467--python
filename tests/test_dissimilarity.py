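import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from reefchrono.binning import ReefZone, TimeBin
from reefchrono.dissimilarity import (
    bh_adjust,
    bin_grand_mean,
    bootstrap_ci,
    compute_series,
    jaccard_dissimilarity,
    pairwise_jaccard,
    pairwise_permutation_tests,
    within_country_mean,
)
from reefchrono.records import SPECIES_COLUMNS, BinnedOccurrenceMatrix


def vec(*present):
    v = np.zeros(len(SPECIES_COLUMNS))
    for name in present:
        v[SPECIES_COLUMNS.index(name)] = 1
    return v


class TestJaccard:
    def test_identical_nonempty_is_zero(self):
        a = vec("ACER", "MCAV")
        assert jaccard_dissimilarity(a, a) == 0.0

    def test_disjoint_is_one(self):
        assert jaccard_dissimilarity(vec("ACER"), vec("MCAV")) == 1.0

    def test_partial_overlap(self):
        a = vec("ACER", "APAL", "ORBICELLA")
        b = vec("ORBICELLA", "AGARICIA")
        assert jaccard_dissimilarity(a, b) == 0.75  # |I|=1, |U|=4

    def test_empty_union_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_dissimilarity(np.zeros(14), np.zeros(14))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            jaccard_dissimilarity(np.full(14, 0.5), vec("ACER"))

    def test_metric_axioms_exhaustive_six_species(self):
        """Symmetry, identity of indiscernibles and the triangle
        inequality over all nonzero 6-bit presence vectors."""
        vecs = np.array(
            [[int(b) for b in np.binary_repr(i, 6)] for i in range(1, 64)], dtype=float
        )
        n = len(vecs)
        inter = vecs @ vecs.T
        sizes = vecs.sum(1)
        union = sizes[:, None] + sizes[None, :] - inter
        D = 1 - inter / union
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        off = D[~np.eye(n, dtype=bool)]
        assert (off > 0).all()  # distinct communities never at distance 0
        lhs = D[:, None, :]  # D(j,k)
        rhs = D[:, :, None] + D[None, :, :]  # D(j,i) + D(i,k) over middle i
        assert (rhs - lhs > -1e-12).all()

    def test_matches_scipy_pdist(self):
        rng = np.random.default_rng(4)
        M = (rng.random((25, 14)) < 0.4).astype(float)
        M[M.sum(axis=1) == 0, 0] = 1  # keep unions nonempty
        ours, skipped = pairwise_jaccard(M)
        assert skipped == 0
        ref = pdist(M.astype(bool), metric="jaccard")
        assert np.allclose(np.sort(ours), np.sort(ref))
        assert np.allclose(ours, ref)


def make_matrix(rows, countries, tb=TimeBin.B1985_1989):
    ids = [f"s{i}" for i in range(len(rows))]
    return BinnedOccurrenceMatrix(
        zone=ReefZone.CREST,
        bin=tb,
        data=pd.DataFrame(rows, index=ids, columns=SPECIES_COLUMNS),
        country=pd.Series(countries, index=ids),
    )


class TestWithinCountry:
    def test_two_sites_single_pair(self):
        m = make_matrix([vec("ACER"), vec("MCAV")], ["CU", "CU"])
        mu, npairs = within_country_mean(m, "CU")
        assert mu == 1.0 and npairs == 1

    def test_three_sites_enumeration(self):
        a, b, c = vec("ACER", "APAL"), vec("ACER"), vec("MCAV")
        m = make_matrix([a, b, c], ["CU"] * 3)
        expected = np.mean(
            [jaccard_dissimilarity(x, y) for x, y in itertools.combinations([a, b, c], 2)]
        )
        mu, npairs = within_country_mean(m, "CU")
        assert mu == pytest.approx(expected)
        assert npairs == 3

    def test_single_site_excluded(self):
        m = make_matrix([vec("ACER"), vec("MCAV")], ["CU", "JM"])
        with pytest.raises(ValueError, match="fewer than 2"):
            within_country_mean(m, "JM")

    def test_empty_pairs_skipped(self):
        m = make_matrix([np.zeros(14), np.zeros(14), vec("ACER")], ["CU"] * 3)
        mu, npairs = within_country_mean(m, "CU")
        assert npairs == 2  # the all-empty pair is dropped
        assert mu == 1.0


class TestGrandMeanAndBootstrap:
    def test_equal_country_weights(self):
        assert bin_grand_mean({"a": 0.2, "b": 0.6}) == pytest.approx(0.4)
        assert bin_grand_mean({"a": 0.3}) == 0.3

    def test_duplicating_sites_does_not_change_grand_mean(self):
        base = [vec("ACER", "APAL"), vec("ACER"), vec("MCAV"), vec("MCAV", "AGARICIA")]
        m1 = make_matrix(base, ["CU", "CU", "JM", "JM"])
        m2 = make_matrix(base + base[:2], ["CU", "CU", "JM", "JM", "CU", "CU"])
        g1 = bin_grand_mean({c: within_country_mean(m1, c)[0] for c in ("CU", "JM")})
        # duplicating CU's sites adds pairs at distance 0 within CU only;
        # JM's contribution (weight 1) is untouched by CU's inflation
        g2 = bin_grand_mean({c: within_country_mean(m2, c)[0] for c in ("CU", "JM")})
        jm1 = within_country_mean(m1, "JM")[0]
        jm2 = within_country_mean(m2, "JM")[0]
        assert jm1 == jm2

    def test_degenerate_bootstrap(self):
        lo, hi = bootstrap_ci({"a": 0.3, "b": 0.3, "c": 0.3}, B=200, seed=0)
        assert lo == hi == 0.3
        lo, hi = bootstrap_ci({"only": 0.42}, B=200, seed=0)
        assert lo == hi == 0.42

    def test_interval_contains_grand_mean(self):
        rng = np.random.default_rng(3)
        means = {f"c{i}": float(v) for i, v in enumerate(rng.uniform(0.3, 0.9, 15))}
        lo, hi = bootstrap_ci(means, B=1000, seed=1)
        assert lo <= bin_grand_mean(means) <= hi

    def test_interval_narrows_with_more_countries(self):
        rng = np.random.default_rng(5)
        widths = {}
        for n in (10, 40):
            ws = []
            for rep in range(40):
                means = {f"c{i}": float(v) for i, v in enumerate(rng.normal(0.5, 0.1, n))}
                lo, hi = bootstrap_ci(means, B=400, seed=rep)
                ws.append(hi - lo)
            widths[n] = np.median(ws)
        assert widths[40] < widths[10]


class TestPermutationTests:
    def test_identical_multisets_give_p_one(self):
        vals = {f"c{i}": v for i, v in enumerate([0.2, 0.4, 0.6, 0.8])}
        series = {TimeBin.B1500_1959: vals, TimeBin.B2005_2011: dict(vals)}
        out = pairwise_permutation_tests(series, B=500, seed=0)
        assert out["raw_p"].iloc[0] == 1.0

    def test_fully_separated_samples_reach_minimal_p(self):
        a = {f"a{i}": 0.1 + 0.01 * i for i in range(10)}
        b = {f"b{i}": 0.7 + 0.01 * i for i in range(10)}
        out = pairwise_permutation_tests(
            {TimeBin.B1500_1959: a, TimeBin.B2005_2011: b}, B=1000, seed=1
        )
        assert out["raw_p"].iloc[0] <= 0.005  # near 1/(B+1)

    def test_small_bins_skipped(self):
        series = {
            TimeBin.B1500_1959: {"a": 0.5, "b": 0.6},
            TimeBin.B1990_1994: {"only": 0.4},
            TimeBin.B2005_2011: {"c": 0.3, "d": 0.4},
        }
        out = pairwise_permutation_tests(series, B=100, seed=0)
        assert len(out) == 1  # only the pair of 2-country bins

    def test_statistic_sign_tracks_mean_difference(self):
        a = {f"a{i}": v for i, v in enumerate([0.7, 0.75, 0.8])}
        b = {f"b{i}": v for i, v in enumerate([0.4, 0.45, 0.5])}
        out = pairwise_permutation_tests(
            {TimeBin.B1500_1959: a, TimeBin.B2005_2011: b}, B=200, seed=0
        )
        assert out["statistic"].iloc[0] > 0  # earlier bin more dissimilar


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_step_up_enumeration(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_order_preserving(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSeries:
    def test_series_on_scenario(self, full_complement_matrices):
        series = compute_series(
            full_complement_matrices, ReefZone.CREST, B=100, seed=0, permutations=200
        )
        t = series.table
        assert (t["grand_mean"].between(0, 1)).all()
        assert (t["ci_low"] <= t["grand_mean"]).all()
        assert (t["grand_mean"] <= t["ci_high"]).all()
        assert (t["n_countries"] >= 1).all()
        comps = series.comparisons
        assert (comps["adjusted_p"] >= comps["raw_p"] - 1e-12).all()

    def test_fossil_bins_more_homogeneous_than_historical(self, full_complement_matrices):
        """Time-averaged fossil bins show lower within-country dissimilarity
        than the 1500-1959 bin."""
        series = compute_series(
            full_complement_matrices, ReefZone.CREST, B=50, seed=0, permutations=None
        )
        g = dict(zip(series.table["bin"], series.table["grand_mean"]))
        assert g["PLEISTOCENE"] < g["B1500_1959"]
        assert g["HOLOCENE"] < g["B1500_1959"]
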