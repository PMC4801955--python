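"""Mock-community quantification: profiles, biomass, correlations, rarefaction."""

import numpy as np
import pytest
from scipy import stats

from dietbarcoder.assign import OtuTable
from dietbarcoder.quantify import (
    BiomassModel,
    CommunityProfile,
    MockDesign,
    among_taxa_correlation,
    counts_to_biomass,
    expected_profiles,
    rarefaction,
    replicate_consistency,
    within_taxon_correlation,
)

from oracles import mannwhitney_permutation_p, rarefaction_enumeration


class TestExpectedProfiles:
    def test_mock_d_dominance(self, table1_design):
        profiles = expected_profiles(table1_design)
        frac = profiles["MOCK-D"].fractions["Meganyctiphanes norvegica"]
        assert frac == pytest.approx(100 / 112)
        assert round(frac * 100) == 89

    def test_mock_c_six_otus_thirteen_individuals(self, table1_design):
        collapsed = table1_design.collapsed_counts()
        assert len(collapsed) == 6
        assert collapsed["MOCK-C"].sum() == 13

    def test_total_individuals(self, table1_design):
        assert table1_design.total_individuals() == 884
        assert table1_design.collapsed_counts().to_numpy().sum() == 884

    def test_group_collapse_preserves_totals(self, table1_design):
        collapsed = table1_design.collapsed_counts()
        assert collapsed.loc["Para-Und-Euch group", "MOCK-B"] == 270

    def test_single_species_sample(self):
        design = MockDesign(
            ["only sp"], ["s1"], np.array([[7]]), {"only sp": 3.0}, {"only sp": 0.1}, {}
        )
        assert expected_profiles(design)["s1"].fractions["only sp"] == 1.0

    def test_empty_sample_raises(self):
        design = MockDesign(
            ["sp"], ["s1"], np.array([[0]]), {"sp": 3.0}, {"sp": 0.1}, {}
        )
        with pytest.raises(ValueError, match="empty-sample"):
            expected_profiles(design)


class TestBiomass:
    def test_closed_form(self):
        model = BiomassModel({"t": (1.0, 0.0)}, carbon_fraction=0.4)
        biomass, _ = counts_to_biomass({"t": 10}, {"t": 5.0}, model)
        assert biomass["t"] == pytest.approx(4.0)

    def test_power_law_ratio(self):
        model = BiomassModel({"a": (1.0, 3.0), "b": (1.0, 3.0)})
        biomass, profile = counts_to_biomass(
            {"a": 10, "b": 10}, {"a": 2.0, "b": 1.0}, model
        )
        assert biomass["a"] / biomass["b"] == pytest.approx(8.0)
        assert profile.fractions["a"] == pytest.approx(8 / 9)

    def test_random_design_matches_hand_computation(self):
        rng = np.random.default_rng(3)
        taxa = ["t%d" % i for i in range(5)]
        model = BiomassModel(
            {t: (float(rng.uniform(0.001, 0.01)), float(rng.uniform(2, 3.5))) for t in taxa},
            carbon_fraction=0.4,
        )
        counts = {t: int(rng.integers(1, 50)) for t in taxa}
        lengths = {t: float(rng.uniform(2, 9)) for t in taxa}
        biomass, profile = counts_to_biomass(counts, lengths, model)
        expected = {
            t: counts[t] * model.coefficients[t][0] * lengths[t] ** model.coefficients[t][1] * 0.4
            for t in taxa
        }
        total = sum(expected.values())
        for t in taxa:
            assert biomass[t] == pytest.approx(expected[t])
            assert profile.fractions[t] == pytest.approx(expected[t] / total)

    def test_missing_coefficients_raise(self):
        model = BiomassModel({"known": (1.0, 2.0)})
        with pytest.raises(KeyError, match="no-model-for-taxon"):
            counts_to_biomass({"unknown": 1}, {"unknown": 2.0}, model)

    def test_packaged_placeholder_model_loads(self):
        import importlib.resources

        path = importlib.resources.files("dietbarcoder.data") / "biomass_models.yaml"
        model = BiomassModel.from_yaml(str(path))
        assert model.carbon_fraction == 0.4
        assert "Meganyctiphanes norvegica" in model.coefficients


class TestCorrelations:
    def test_proportional_vectors_r_one(self):
        ref = [0.1, 0.4, 0.2, 0.3]
        obs = [0.2, 0.8, 0.4, 0.6]
        r, p = within_taxon_correlation(ref, obs)
        assert r == pytest.approx(1.0)

    def test_reversed_reference_negative(self):
        ref = [0.1, 0.2, 0.3, 0.4]
        r, _ = within_taxon_correlation(ref, ref[::-1])
        assert r < 0

    def test_degenerate_vector_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            within_taxon_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])

    def test_identical_profiles_r_one(self):
        prof = CommunityProfile("s", "counts", {"a": 0.5, "b": 0.3, "c": 0.2})
        r, p = among_taxa_correlation(prof, prof)
        assert r == pytest.approx(1.0)

    def test_two_otus_degenerate_small(self):
        a = CommunityProfile("s", "counts", {"a": 0.7, "b": 0.3})
        with pytest.raises(ValueError, match="degenerate-small"):
            among_taxa_correlation(a, a)


class TestReplicateConsistency:
    def test_identical_replicates_all_h_zero(self):
        counts = np.tile(np.array([10, 5, 1]), (4, 1))
        table = OtuTable(["r1", "r2", "r3", "r4"], ["a", "b", "c"], counts)
        df = replicate_consistency(table, {"g1": ["r1", "r2"], "g2": ["r3", "r4"]})
        assert (df["H"] == 0).all()
        assert df.attrs["significant_fraction"] == 0.0

    def test_two_group_h_equals_z_squared(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(1, 100, size=(8, 5))
        table = OtuTable(["s%d" % i for i in range(8)], ["o%d" % j for j in range(5)], counts)
        groups = {"g1": table.samples[:4], "g2": table.samples[4:]}
        df = replicate_consistency(table, groups)
        rel = table.relative_abundance()
        for j, otu in enumerate(table.otus):
            x, y = rel[:4, j], rel[4:, j]
            z = stats.ranksums(x, y).statistic
            assert df.loc[df["otu"] == otu, "H"].iloc[0] == pytest.approx(z**2)

    def test_planted_shift_detected_vs_permutation_oracle(self):
        # note: relative abundances are compositional, so a strong shift in
        # one OTU systematically depresses the others; only the planted OTU
        # is required to be flagged, and it must carry the smallest p
        rng = np.random.default_rng(19)
        base = rng.integers(20, 120, size=(8, 20)).astype(float)
        base[4:, 0] *= 5  # plant a shifted OTU in group 2
        table = OtuTable(
            ["s%d" % i for i in range(8)], ["o%d" % j for j in range(20)],
            base.astype(int),
        )
        groups = {"g1": table.samples[:4], "g2": table.samples[4:]}
        df = replicate_consistency(table, groups).set_index("otu")
        assert df.loc["o0", "p"] < 0.05
        assert df.loc["o0", "p"] == df["p"].min()
        rel = table.relative_abundance()
        p_perm = mannwhitney_permutation_p(rel[:4, 0], rel[4:, 0], n_perm=10000)
        assert (df.loc["o0", "p"] < 0.05) == (p_perm < 0.05)


class TestRarefaction:
    def test_full_depth_gives_observed_richness(self):
        df = rarefaction([5, 3, 2], [10])
        assert df["expected_otus"].iloc[0] == pytest.approx(3.0)

    def test_depth_one(self):
        df = rarefaction([5, 3, 2], [1])
        assert df["expected_otus"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        df = rarefaction([5, 3, 2], [4])
        assert df["expected_otus"].iloc[0] == pytest.approx(
            rarefaction_enumeration([5, 3, 2], 4)
        )

    def test_depth_exceeds_sample_raises(self):
        with pytest.raises(ValueError, match="depth-exceeds-sample"):
            rarefaction([5, 3, 2], [11])

    def test_curve_nondecreasing_and_concave(self, rng):
        counts = rng.integers(1, 200, size=12)
        depths = np.arange(1, int(counts.sum()) + 1, 17)
        vals = rarefaction(counts, depths)["expected_otus"].to_numpy()
        diffs = np.diff(vals)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()
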