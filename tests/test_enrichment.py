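"""Enrichment factors, calling, Bray-Curtis, PERMANOVA and PCoA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from agscope import (
    AbundanceTable,
    CommunitySimSpec,
    benjamini_hochberg,
    bray_curtis,
    bray_curtis_matrix,
    call_enrichment,
    ef_table,
    enrichment_factor,
    gen_community,
    pcoa,
    permanova,
    relative_abundance,
)


def _table(counts_rows, donors, treatments, timepoints, genera=None):
    n = len(counts_rows)
    genera = genera or [f"g{i}" for i in range(len(counts_rows[0]))]
    idx = [f"s{i}" for i in range(n)]
    counts = pd.DataFrame(counts_rows, index=idx, columns=genera)
    meta = pd.DataFrame(
        {"donor": donors, "treatment": treatments, "timepoint": timepoints}, index=idx
    )
    return AbundanceTable(counts=counts, sample_meta=meta)


class TestRelativeAbundance:
    def test_hand_proportions(self):
        t = _table([[1, 2, 7]], ["d1"], ["NA"], [0.0])
        ra = relative_abundance(t)
        assert np.allclose(ra.iloc[0], [0.1, 0.2, 0.7])

    def test_rows_sum_to_one(self, planted_community):
        ra = relative_abundance(planted_community)
        assert np.allclose(ra.sum(axis=1), 1.0)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            _table([[0, 0]], ["d1"], ["NA"], [0.0])


class TestEnrichmentFactor:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (0.3, 0.3, 0.0),
            (0.5, 0.0, 1.0),
            (0.0, 0.5, -1.0),
            (0.02, 0.04, -1.0 / 3.0),
            (0.0, 0.0, 0.0),  # 0/0 convention
        ],
    )
    def test_known_values(self, a, b, expected):
        assert enrichment_factor(a, b) == pytest.approx(expected)

    def test_negative_input_errors(self):
        with pytest.raises(ValueError):
            enrichment_factor(-0.1, 0.2)

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bounded_and_antisymmetric(self, a, b):
        ef = enrichment_factor(a, b)
        assert -1.0 <= ef <= 1.0
        assert enrichment_factor(b, a) == pytest.approx(-ef, abs=1e-12)

    @given(b=st.floats(0.01, 1), a1=st.floats(0, 1), a2=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_treated_abundance(self, b, a1, a2):
        lo, hi = sorted([a1, a2])
        assert enrichment_factor(hi, b) >= enrichment_factor(lo, b) - 1e-12


class TestEfTable:
    def test_identical_treated_and_control_all_zero(self):
        row = [10, 20, 30]
        t = _table(
            [row, row, row, row],
            ["d1", "d1", "d2", "d2"],
            ["AG", "NA", "AG", "NA"],
            [6.0, 6.0, 6.0, 6.0],
        )
        res = ef_table(t, "AG", 6.0)
        assert np.allclose(res.ef["ef"], 0.0)

    def test_missing_donor_pair_errors_listing_donor(self):
        t = _table(
            [[10, 20], [10, 20], [5, 5]],
            ["d1", "d1", "d2"],
            ["AG", "NA", "AG"],
            [6.0, 6.0, 6.0],
        )
        with pytest.raises(ValueError, match="d2"):
            ef_table(t, "AG", 6.0)

    def test_opposite_donor_effects_cancel(self):
        t = _table(
            [[3, 7], [1, 9], [1, 9], [3, 7]],
            ["d1", "d1", "d2", "d2"],
            ["AG", "NA", "AG", "NA"],
            [6.0] * 4,
        )
        res = ef_table(t, "AG", 6.0)
        mean_ef = res.ef.groupby("genus")["ef"].mean()
        assert np.allclose(mean_ef, 0.0, atol=1e-12)

    def test_planted_genus_has_largest_mean_ef(self):
        t = gen_community(
            CommunitySimSpec(n_donors=10, n_genera=20, depth=20_000,
                             enriched_genera=frozenset({5}), effect_multiplier=4.0, seed=3)
        )
        res = ef_table(t, "AG", 6.0)
        mean_ef = res.ef.groupby("genus")["ef"].mean()
        assert mean_ef.idxmax() == "g005"


class TestCallEnrichment:
    def test_all_zero_efs_give_no_calls(self):
        row = [10, 20, 30]
        t = _table([row] * 4, ["d1", "d1", "d2", "d2"],
                   ["AG", "NA", "AG", "NA"], [6.0] * 4)
        res = call_enrichment(ef_table(t, "AG", 6.0))
        assert not res.calls["enriched"].any()

    def test_unanimous_strong_effect_called_enriched(self):
        # EF +0.9 in every donor: SD floor keeps z finite and extreme
        ef = pd.DataFrame(
            [{"genus": "g", "donor": f"d{i}", "ef": 0.9} for i in range(10)]
            + [{"genus": "h", "donor": f"d{i}", "ef": 0.0} for i in range(10)]
        )
        from agscope.enrichment import EnrichmentResult

        res = EnrichmentResult(
            treatment="AG", timepoint=6.0, ef=ef,
            baseline_ra=pd.Series({"g": 0.1, "h": 0.1}),
        )
        out = call_enrichment(res)
        assert bool(out.calls.loc["g", "enriched"])
        assert np.isfinite(out.calls.loc["g", "z"])
        assert not bool(out.calls.loc["h", "enriched"])

    def test_single_donor_errors(self):
        t = _table([[1, 2], [2, 1]], ["d1", "d1"], ["AG", "NA"], [6.0, 6.0])
        with pytest.raises(ValueError, match=">= 2 donors"):
            call_enrichment(ef_table(t, "AG", 6.0))

    def test_planted_simulation_recovery(self, planted_community):
        res = call_enrichment(ef_table(planted_community, "AG", 6.0))
        called = set(res.calls.index[res.calls["enriched"]])
        assert {"g001", "g002", "g003"} <= called


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_step_up_case(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        assert bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_matches_pairwise(self, rng):
        prof = pd.DataFrame(rng.dirichlet(np.ones(5), 6))
        dm = bray_curtis_matrix(prof)
        for i in range(6):
            for j in range(6):
                assert dm.iloc[i, j] == pytest.approx(
                    0.0 if i == j else bray_curtis(prof.iloc[i], prof.iloc[j])
                )


class TestPermanova:
    def test_matches_skbio_single_factor(self, rng):
        prof = pd.DataFrame(rng.dirichlet(np.ones(8), 16))
        meta = pd.DataFrame({"treatment": ["X"] * 8 + ["Y"] * 8})
        dm = bray_curtis_matrix(prof)
        mine = permanova(dm, meta, ["treatment"], n_perm=199, seed=0)
        ref = skbio_permanova(
            DistanceMatrix(dm.to_numpy()), meta["treatment"].to_numpy(), permutations=199
        )
        assert mine.terms.loc["treatment", "pseudo_f"] == pytest.approx(
            ref["test statistic"], rel=1e-9
        )

    def test_r2_partition_sums_to_one(self, planted_community):
        dm = bray_curtis_matrix(relative_abundance(planted_community))
        res = permanova(dm, planted_community.sample_meta, ["donor", "treatment"],
                        n_perm=99, seed=1)
        assert res.terms["r2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert ((res.terms["r2"] >= -1e-12) & (res.terms["r2"] <= 1 + 1e-12)).all()

    def test_fully_separated_groups(self):
        prof = pd.DataFrame([[1, 0, 0, 0]] * 10 + [[0, 0, 0, 1]] * 10, dtype=float)
        meta = pd.DataFrame({"treatment": ["A"] * 10 + ["B"] * 10})
        dm = bray_curtis_matrix(prof)
        res = permanova(dm, meta, ["treatment"], n_perm=199, seed=0)
        assert res.terms.loc["treatment", "r2"] > 0.95
        # permutations that preserve the two-group partition reproduce the
        # observed (infinite) F exactly and tie; the p-value is minimal up
        # to those ties, counted here from the same permutation stream
        rng = np.random.default_rng(0)
        ties = sum(
            set(rng.permutation(20)[:10]) in ({*range(10)}, {*range(10, 20)})
            for _ in range(199)
        )
        assert res.terms.loc["treatment", "p"] == pytest.approx((1.0 + ties) / 200.0)

    def test_single_level_term_errors(self):
        prof = pd.DataFrame(np.random.default_rng(1).dirichlet(np.ones(4), 6))
        meta = pd.DataFrame({"treatment": ["A"] * 6})
        dm = bray_curtis_matrix(prof)
        with pytest.raises(ValueError, match="single level"):
            permanova(dm, meta, ["treatment"], n_perm=99)

    def test_donor_term_absorbs_donor_structure(self):
        t = gen_community(
            CommunitySimSpec(n_donors=6, n_genera=15, depth=10_000,
                             effect_multiplier=1.0, donor_logmean_sd=2.0, seed=4)
        )
        dm = bray_curtis_matrix(relative_abundance(t))
        res = permanova(dm, t.sample_meta, ["donor", "treatment"], n_perm=99, seed=2)
        assert res.terms.loc["donor", "r2"] > res.terms.loc["treatment", "r2"]
        assert res.terms.loc["treatment", "r2"] < 0.1


class TestPcoa:
    def test_three_collinear_points(self):
        # points at 0, 1, 2 on a line: distances 1, 1, 2
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords, eigvals = pcoa(d)
        assert coords.shape[1] == 1
        spacing = np.sort(coords.iloc[:, 0].to_numpy())
        assert np.allclose(np.diff(spacing), 1.0, atol=1e-9)

    def test_identical_samples_no_positive_axes(self):
        d = np.zeros((4, 4))
        coords, eigvals = pcoa(d)
        assert coords.shape[1] == 0

    def test_round_trip_on_euclidean_distances(self, rng):
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        coords, _ = pcoa(d)
        d2 = squareform(pdist(coords.to_numpy()[:, :2]))
        assert np.allclose(d, d2, atol=1e-6)
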