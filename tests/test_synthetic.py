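"""Generator behavior: determinism, calibration to profile parameters,
conservation, and the statistical structure the analysis stages assume."""

import numpy as np
import pandas as pd
import pytest

from ctcemt.calibration import fit_linearity
from ctcemt.records import (
    REFERENCE_PROFILES,
    CellLineProfile,
    ConfigError,
    GenerationError,
)
from ctcemt.synthetic import (
    BeadGenConfig,
    CohortGenConfig,
    CytospinLayout,
    generate_beads,
    generate_cellline_cells,
    generate_cohort,
    generate_cytospin_image,
)


class TestBeads:
    def test_noise_free_proportionality_below_saturation(self):
        cfg = BeadGenConfig(
            pmt_voltages=(500.0,),
            nominal_levels=(1.0, 0.5),
            noise_cv=0.0,
            replicates_per_level=1,
            saturation_voltage=560.0,
            seed=0,
        )
        df = generate_beads(cfg)
        hi = df.loc[df.nominal_level == 1.0, "measured"].item()
        lo = df.loc[df.nominal_level == 0.5, "measured"].item()
        assert hi == pytest.approx(2.0 * lo)

    def test_row_count(self):
        df = generate_beads(BeadGenConfig(replicates_per_level=3))
        assert len(df) == 4 * 4 * 3
        assert (df.groupby("pmt_voltage").size() == 12).all()

    def test_saturation_degrades_linearity(self):
        df = generate_beads(BeadGenConfig(saturation_voltage=560.0, seed=1))
        fits = {f.pmt_voltage: f.r_squared for f in fit_linearity(df)}
        assert fits[600.0] < fits[550.0]

    def test_noise_free_linearity_is_exact_below_saturation(self):
        df = generate_beads(BeadGenConfig(noise_cv=0.0, seed=3))
        for f in fit_linearity(df):
            if f.pmt_voltage <= 560.0:
                assert f.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            BeadGenConfig(pmt_voltages=())
        with pytest.raises(ConfigError):
            BeadGenConfig(nominal_levels=(0.1, 0.5))  # not decreasing
        with pytest.raises(ConfigError):
            BeadGenConfig(pmt_voltages=(-450.0,))

    def test_deterministic_under_seed(self):
        a = generate_beads(BeadGenConfig(seed=7))
        b = generate_beads(BeadGenConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)


class TestCellLineCells:
    def test_mcf7_ratios_inside_reference_range(self):
        cells = generate_cellline_cells(REFERENCE_PROFILES["MCF-7"], 100, seed=7)
        ratios = np.array(
            [c.mean_intensity["vimentin"] / c.mean_intensity["keratin"] for c in cells]
        )
        assert len(cells) == 100
        assert ratios.min() >= 0.12 and ratios.max() <= 0.49

    def test_zero_vimentin_gives_zero_ratio(self):
        profile = CellLineProfile("novim", 50.0, 5.0, 0.0, 0.0)
        cells = generate_cellline_cells(profile, 20, seed=0)
        assert all(c.mean_intensity["vimentin"] == 0.0 for c in cells)

    def test_hs578t_keratin_mean_recovered(self):
        p = REFERENCE_PROFILES["Hs578T"]
        cells = generate_cellline_cells(p, 500, seed=3)
        k = np.array([c.mean_intensity["keratin"] for c in cells])
        se = p.keratin_sd / np.sqrt(500)
        assert abs(k.mean() - 4.02) < 3 * se

    @pytest.mark.parametrize("name", sorted(REFERENCE_PROFILES))
    def test_marginal_calibration_at_n1000(self, name):
        """Post-rejection marginal means/SDs match profile parameters (4 SE)."""
        p = REFERENCE_PROFILES[name]
        cells = generate_cellline_cells(p, 1000, seed=42)
        for marker, mean, sd in (
            ("keratin", p.keratin_mean, p.keratin_sd),
            ("vimentin", p.vimentin_mean, p.vimentin_sd),
        ):
            x = np.array([c.mean_intensity[marker] for c in cells])
            se_mean = sd / np.sqrt(len(x))
            se_sd = sd / np.sqrt(2 * (len(x) - 1))
            assert abs(x.mean() - mean) < 4 * se_mean, (name, marker, "mean")
            assert abs(x.std(ddof=1) - sd) < 4 * se_sd, (name, marker, "sd")

    def test_infeasible_ratio_range_raises(self):
        bad = CellLineProfile(
            "bad", 100.0, 5.0, 1.0, 0.1, ratio_range=(50.0, 60.0)
        )
        with pytest.raises(GenerationError, match="bad"):
            generate_cellline_cells(bad, 10, seed=0)

    def test_deterministic_under_seed(self):
        a = generate_cellline_cells(REFERENCE_PROFILES["T47D"], 50, seed=5)
        b = generate_cellline_cells(REFERENCE_PROFILES["T47D"], 50, seed=5)
        assert [c.ctcf for c in a] == [c.ctcf for c in b]


class TestCytospin:
    def test_ground_truth_counts_and_identity(self):
        layout = CytospinLayout(n_ctcs=0, n_pbmcs=5, seed=2)
        _, truth = generate_cytospin_image(layout, REFERENCE_PROFILES["MCF-7"])
        assert len(truth) == 5
        assert (~truth["is_ctc"]).all()

    def test_signal_conservation_without_background_or_noise(self):
        layout = CytospinLayout(
            n_ctcs=3, n_pbmcs=10, background_level=0.0, noise_sd=0.0, seed=4
        )
        image, truth = generate_cytospin_image(layout, REFERENCE_PROFILES["MCF-7"])
        keratin = image[list(layout.channel_names).index("keratin")]
        assert keratin.sum() == pytest.approx(truth["total_keratin"].sum(), rel=1e-6)

    def test_intensities_within_bit_depth(self, cytospin_fixture):
        layout, image, _ = cytospin_fixture
        assert image.min() >= 0 and image.max() <= 2**layout.bit_depth - 1

    def test_infeasible_layout_raises(self):
        with pytest.raises(GenerationError):
            generate_cytospin_image(
                CytospinLayout(image_shape=(64, 64), n_ctcs=20, n_pbmcs=20, seed=0),
                REFERENCE_PROFILES["MCF-7"],
            )

    def test_deterministic_under_seed(self):
        layout = CytospinLayout(seed=9)
        a, _ = generate_cytospin_image(layout, REFERENCE_PROFILES["MCF-7"])
        b, _ = generate_cytospin_image(layout, REFERENCE_PROFILES["MCF-7"])
        assert np.array_equal(a, b)


class TestCohort:
    def test_cohort_size_and_inclusion_rule(self):
        patients = generate_cohort(CohortGenConfig(n_patients=61, seed=1))
        assert len(patients) == 61
        assert all(len(p.ctc_keratin_values) >= 2 for p in patients)

    def test_tn_keratin_mean_difference_recovered(self):
        cfg = CohortGenConfig(
            n_patients=200,
            keratin_mean_tn=122.4,
            keratin_mean_other=175.0,
            seed=5,
        )
        patients = generate_cohort(cfg)
        tn = np.concatenate(
            [p.ctc_keratin_values for p in patients if p.triple_negative]
        )
        other = np.concatenate(
            [p.ctc_keratin_values for p in patients if not p.triple_negative]
        )
        diff = other.mean() - tn.mean()
        se = cfg.keratin_sd * np.sqrt(1 / tn.size + 1 / other.size)
        assert abs(diff - (175.0 - 122.4)) < 3 * se

    def test_null_survival_configuration(self):
        """Equal per-stratum survival targets: log-rank should not reject."""
        from ctcemt.cohort import analyze_cohort

        cfg = CohortGenConfig(
            n_patients=150, one_year_surv_hk=0.6, one_year_surv_lk=0.6, seed=11
        )
        res = analyze_cohort(generate_cohort(cfg))
        assert res.survival.logrank_p > 0.05

    def test_receptor_status_consistency(self):
        for p in generate_cohort(CohortGenConfig(n_patients=100, seed=3)):
            statuses = (p.er_status, p.pr_status, p.her2_status)
            if p.triple_negative:
                assert statuses == ("negative",) * 3
            else:
                assert "positive" in statuses

    def test_deterministic_under_seed(self):
        a = generate_cohort(CohortGenConfig(seed=6))
        b = generate_cohort(CohortGenConfig(seed=6))
        assert all(
            x.ctc_keratin_values == y.ctc_keratin_values and x.os_months == y.os_months
            for x, y in zip(a, b)
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortGenConfig(ctcs_per_patient_range=(1, 5))
        with pytest.raises(ConfigError):
            CohortGenConfig(tn_fraction=1.5)
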