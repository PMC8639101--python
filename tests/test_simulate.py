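"""Statistical structure of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from cgpval.simulate import (
    SimulationConfig,
    TruthSample,
    TruthVariant,
    depth_lognormal_params,
    draw_depths,
    draw_genotypes,
    make_truth_sample,
    simulate_contamination,
    simulate_dilution_series,
    simulate_msi_sites,
    simulate_variant_table,
)


def somatic(pos, ccf=1.0, **kwargs):
    return TruthVariant(
        chrom="chr1", pos=pos, ref="A", alt="T", gene="TP53",
        cellular_fraction=ccf, **kwargs,
    )


class TestDepthModel:
    def test_matches_configured_median_and_sd(self, rng):
        config = SimulationConfig()
        depths = draw_depths(200_000, config, rng)
        assert np.median(depths) == pytest.approx(750, rel=0.02)
        assert np.std(depths) == pytest.approx(385, rel=0.05)
        assert (depths >= 0).all()
        assert depths.dtype.kind == "i"

    def test_closed_form_parameters(self):
        mu, sigma = depth_lognormal_params(750, 385)
        assert np.exp(mu) == pytest.approx(750)
        # implied SD of the log-normal reproduces the input
        implied_var = 750**2 * np.exp(sigma**2) * (np.exp(sigma**2) - 1)
        assert np.sqrt(implied_var) == pytest.approx(385)

    def test_right_skewed(self, rng):
        depths = draw_depths(100_000, SimulationConfig(), rng)
        assert depths.mean() > np.median(depths)


class TestVariantTable:
    def test_no_somatic_no_error_emits_only_germline_rows(self, rng):
        truth = TruthSample(
            sample_id="S1", purity=0.5,
            variants=(somatic(1, germline=True), somatic(2, germline=True)),
        )
        config = SimulationConfig(sequencing_error=0.0, n_decoy_loci=0)
        table = simulate_variant_table(truth, config, rng)
        assert len(table) == 2
        assert table["germline"].all()

    def test_mean_vaf_matches_closed_form(self, rng):
        """purity 0.5 x ccf 1 x dosage 0.5 -> expected VAF 0.25, checked
        over >=10,000 independent locus draws within 3 Monte-Carlo SE."""
        truth = TruthSample(
            sample_id="S1", purity=0.5,
            variants=tuple(somatic(pos) for pos in range(1, 10_001)),
        )
        config = SimulationConfig(n_decoy_loci=0)
        table = simulate_variant_table(truth, config, rng)
        se = table["vaf"].std() / np.sqrt(len(table))
        assert abs(table["vaf"].mean() - 0.25) < 3 * se

    def test_germline_vaf_independent_of_purity(self, rng):
        truth = TruthSample(
            sample_id="S1", purity=0.05,
            variants=tuple(
                somatic(pos, germline=True, allele_dosage=0.5) for pos in range(1, 2001)
            ),
        )
        table = simulate_variant_table(truth, SimulationConfig(n_decoy_loci=0), rng)
        assert table["vaf"].mean() == pytest.approx(0.5, abs=0.01)

    def test_fixed_seed_reproduces_byte_identical_tables(self):
        truth = make_truth_sample("S1", np.random.default_rng(5), purity=0.6)
        t1 = simulate_variant_table(truth, SimulationConfig(seed=42))
        t2 = simulate_variant_table(truth, SimulationConfig(seed=42))
        assert t1.to_csv() == t2.to_csv()

    def test_decoy_rows_have_no_truth_signal(self, fast_sim, rng):
        truth = TruthSample(sample_id="S1", purity=0.5, variants=(somatic(1),))
        table = simulate_variant_table(truth, fast_sim, rng)
        decoys = table[table["gene"] == "NONE"]
        assert len(decoys) == fast_sim.n_decoy_loci
        assert (decoys["expected_vaf"] == 0).all()
        assert not decoys["truth_positive"].any()

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            TruthSample(sample_id="S1", purity=float("nan"))
        with pytest.raises(ValueError):
            TruthSample(sample_id="S1", purity=0.5, tmb_rate=float("inf"))
        with pytest.raises(ValueError):
            TruthVariant(chrom="1", pos=1, ref="A", alt="T", gene="X", cellular_fraction=0.0)


class TestDilutionSeries:
    def truth(self):
        return TruthSample(
            sample_id="S1", purity=0.4,
            variants=(somatic(1, ccf=0.5), somatic(2, germline=True)),
        )

    def test_neat_level_preserves_expected_vafs(self, fast_sim, rng):
        table = simulate_dilution_series(self.truth(), [1.0], 2, fast_sim, rng)
        somatic_rows = table[table["gene"] == "TP53"]
        neat = somatic_rows[~somatic_rows["germline"]]
        assert np.allclose(neat["expected_vaf"], 0.4 * 0.5 * 0.5)

    def test_expected_vaf_scales_linearly_with_level(self, fast_sim, rng):
        table = simulate_dilution_series(self.truth(), [1.0, 0.5], 1, fast_sim, rng)
        by_level = table[~table["germline"] & (table["gene"] == "TP53")].groupby("level")[
            "expected_vaf"
        ].first()
        assert by_level[0.5] == pytest.approx(0.5 * by_level[1.0])

    def test_one_in_32_dilution_of_96_percent_purity(self):
        assert 0.96 / 32 == pytest.approx(0.03)

    def test_germline_rows_unscaled(self, fast_sim, rng):
        table = simulate_dilution_series(self.truth(), [1.0, 0.25], 1, fast_sim, rng)
        germ = table[table["germline"]]
        assert (germ["expected_vaf"] == 0.5).all()

    def test_zero_level_rejected(self, fast_sim, rng):
        with pytest.raises(ValueError):
            simulate_dilution_series(self.truth(), [1.0, 0.0], 1, fast_sim, rng)

    def test_unsorted_levels_rejected(self, fast_sim, rng):
        with pytest.raises(ValueError):
            simulate_dilution_series(self.truth(), [0.5, 1.0], 1, fast_sim, rng)


class TestMsiSites:
    def test_stable_truth_has_no_unstable_sites(self, rng):
        truth = TruthSample(sample_id="S1", purity=0.9, msi_status="MS-Stable")
        sites = simulate_msi_sites(truth, SimulationConfig(), rng)
        assert len(sites) == 130
        assert not sites["truth_unstable"].any()

    def test_msi_high_at_high_purity_exceeds_cutoff(self, rng):
        truth = TruthSample(sample_id="S1", purity=0.9, msi_status="MSI-High")
        sites = simulate_msi_sites(truth, SimulationConfig(), rng)
        assert sites["truth_unstable"].mean() > 0.20
        # the shifted statistics separate from baseline
        assert sites.loc[sites["truth_unstable"], "instability_statistic"].mean() > 3

    def test_zero_purity_indistinguishable_from_baseline(self, rng):
        truth = TruthSample(sample_id="S1", purity=0.0, msi_status="MSI-High")
        sites = simulate_msi_sites(truth, SimulationConfig(), rng)
        assert not sites["truth_unstable"].any()
        assert abs(sites["instability_statistic"].mean()) < 3 / np.sqrt(130)


class TestContamination:
    def test_alpha_zero_expected_vafs_are_germline_clean(self, rng):
        ga = draw_genotypes(200, 0.3, rng)
        table = simulate_contamination(ga, ga[::-1].copy(), 0.0, SimulationConfig(), rng)
        assert set(table["expected_vaf"]).issubset({0.0, 0.5, 1.0})

    def test_alpha_one_equals_pure_contaminant(self, rng):
        ga = draw_genotypes(200, 0.3, rng)
        gb = draw_genotypes(200, 0.3, rng)
        table = simulate_contamination(ga, gb, 1.0, SimulationConfig(), rng)
        assert (table["expected_vaf"] == gb / 2).all()

    def test_mixture_formula_hom_ref_host_het_contaminant(self, rng):
        ga = np.zeros(10, dtype=int)
        gb = np.ones(10, dtype=int)
        table = simulate_contamination(ga, gb, 0.1, SimulationConfig(), rng)
        assert np.allclose(table["expected_vaf"], 0.05)

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_contamination(np.zeros(3, int), np.zeros(4, int), 0.1, rng=rng)


class TestMakeTruthSample:
    def test_variant_count_tracks_tmb_rate(self, rng):
        counts = [
            sum(1 for v in make_truth_sample(f"S{i}", rng, tmb_rate=10.0).variants if not v.germline)
            for i in range(40)
        ]
        # Poisson(10 * 1.33) mean 13.3
        assert np.mean(counts) == pytest.approx(13.3, abs=3 * np.sqrt(13.3 / 40))

    def test_tier1_and_germline_planting(self, rng):
        truth = make_truth_sample("S1", rng, tmb_rate=20.0, n_tier1=3, n_germline=10)
        assert sum(v.tier1 for v in truth.variants) == 3
        assert sum(v.germline for v in truth.variants) == 10
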