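"""Synthetic TICs, cine loops and two-arm study tables."""

import numpy as np
import pytest

from ceusquant import (
    BolusModelParams,
    FitConfig,
    StudyConfig,
    evaluate_model,
    extract_parameters,
    extract_tic,
    fit_bolus_model,
    simulate_cine,
    simulate_study,
    simulate_tic,
)
from ceusquant.synthetic_data import (
    CEUS_PARAMETERS,
    US_PARAMETERS,
    back_solve_area,
    study_tics,
)
from ceusquant.tic_model import FitResult


class TestSimulateTic:
    def test_zero_noise_is_exact_model(self, canonical_params):
        tic = simulate_tic(canonical_params, duration=10.0, frame_rate=36.0)
        np.testing.assert_array_equal(
            tic.intensities, evaluate_model(canonical_params, tic.times))
        assert tic.n == 360

    def test_same_seed_same_curve(self, canonical_params):
        a = simulate_tic(canonical_params, noise_sd=1.0, seed=42)
        b = simulate_tic(canonical_params, noise_sd=1.0, seed=42)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        c = simulate_tic(canonical_params, noise_sd=1.0, seed=43)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_realised_noise_level(self, canonical_params):
        """Over the full 1980-frame record the realised noise sd matches
        the requested level within 5%."""
        clean = simulate_tic(canonical_params)
        noisy = simulate_tic(canonical_params, noise_sd=0.6, seed=9)
        resid = noisy.intensities - clean.intensities
        assert resid.std(ddof=1) == pytest.approx(0.6, rel=0.05)

    def test_negative_noise_rejected(self, canonical_params):
        with pytest.raises(ValueError):
            simulate_tic(canonical_params, noise_sd=-1.0)


class TestSimulateCine:
    def test_noiseless_roundtrip_is_machine_exact(self, canonical_params):
        cine, roi = simulate_cine(canonical_params, duration=3.0,
                                  frame_rate=12.0, noise_sd=0.0, seed=0)
        tic = extract_tic(cine, roi)
        np.testing.assert_allclose(
            tic.intensities, evaluate_model(canonical_params, tic.times),
            rtol=1e-13)

    def test_mask_area_matches_ellipse(self, canonical_params):
        """Planted mask area approximates pi*a*b within a perimeter-sized
        discretisation margin."""
        d_mm, ratio, px = 2.0, 0.7, 0.05
        _, roi = simulate_cine(canonical_params, ovary_diameter_mm=d_mm,
                               axis_ratio=ratio, pixel_size_mm=px,
                               duration=0.5, frame_rate=36.0)
        a = 0.5 * d_mm / px
        b = 0.5 * d_mm * ratio / px
        expected = np.pi * a * b
        perimeter = 2 * np.pi * np.sqrt((a * a + b * b) / 2)
        assert abs(roi.n_pixels - expected) < perimeter

    def test_background_is_static_speckle(self, canonical_params):
        cine, roi = simulate_cine(canonical_params, duration=1.0,
                                  frame_rate=36.0, speckle_sd=0.1, seed=4)
        outside = ~roi.mask
        bg = cine.frames[:, outside]
        np.testing.assert_array_equal(bg, np.broadcast_to(bg[0], bg.shape))
        assert bg[0].std() > 0  # speckled, not flat

    def test_oversized_ovary_rejected(self, canonical_params):
        with pytest.raises(ValueError, match="does not fit"):
            simulate_cine(canonical_params, ovary_diameter_mm=5.0,
                          pixel_size_mm=0.05, field_shape=(64, 64),
                          duration=0.5)


class TestBackSolve:
    def test_inverts_peak_enhancement(self):
        pe = 87.25
        A = back_solve_area(pe, mu=np.log(6.0), sigma=0.5)
        p = BolusModelParams(O=5.0, A=A, mu=np.log(6.0), sigma=0.5, t0=2.0)
        fit = FitResult(params=p, rss=0.0, converged=True, n_starts=1,
                        time_origin=0.0)
        assert extract_parameters(fit).pe == pytest.approx(pe, rel=1e-12)


class TestSimulateStudy:
    def test_row_count(self):
        cfg = StudyConfig(n_per_group=2, timepoints=("day10",), seed=0)
        study = simulate_study(cfg)
        assert len(study) == 4
        assert set(study["arm"]) == {"decapeptyl", "control"}

    def test_deterministic_under_seed(self):
        a = simulate_study(StudyConfig(seed=7))
        b = simulate_study(StudyConfig(seed=7))
        assert a.equals(b)

    def test_all_measurements_positive(self):
        study = simulate_study(StudyConfig(seed=1))
        cols = list(US_PARAMETERS) + list(CEUS_PARAMETERS)
        assert (study[cols] > 0).all().all()

    def test_day10_follicle_group_means_on_target(self):
        """Day-10 dominant-follicle draws are centred on the configured
        group means (0.659 and 0.170 mm): the mean pooled over 25 seeded
        studies lands within 3 standard errors of the target."""
        pooled = {"decapeptyl": [], "control": []}
        for s in range(25):
            study = simulate_study(StudyConfig(seed=s))
            d10 = study[study["timepoint"] == "day10"]
            for arm in pooled:
                pooled[arm].extend(
                    d10.loc[d10["arm"] == arm, "follicle_diameter_mm"])
        for arm, mean, sd in (("decapeptyl", 0.659, 0.07),
                              ("control", 0.170, 0.05)):
            vals = np.asarray(pooled[arm])
            assert abs(vals.mean() - mean) < 3 * sd / np.sqrt(vals.size)
            assert vals.std(ddof=1) == pytest.approx(sd, rel=0.2)

    def test_ground_truth_pe_recovered_by_fitting(self):
        """The recorded true PE is reproduced by fitting the noiseless
        generated TIC and extracting parameters."""
        cfg = StudyConfig(n_per_group=2, timepoints=("day20",), seed=5,
                          tic_noise_frac=0.0, duration_s=40.0, frame_rate=12.0)
        study = simulate_study(cfg)
        row = study.iloc[0]
        _, tic = next(study_tics(study, cfg))
        fit = fit_bolus_model(tic, FitConfig(seed=0))
        pp = extract_parameters(fit)
        assert pp.pe == pytest.approx(row["true_pe"], rel=0.01)
        assert pp.auc == pytest.approx(row["true_auc"], rel=0.01)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(n_per_group=1)
        bad = {"pe": {"day0": {"decapeptyl": (10.0, 0.0),
                               "control": (10.0, 1.0)}}}
        with pytest.raises(ValueError):
            StudyConfig(group_effects=bad, timepoints=("day0",))


class TestStudyTics:
    def test_one_curve_per_row_with_metadata(self):
        cfg = StudyConfig(n_per_group=2, timepoints=("day0",), seed=2,
                          duration_s=2.0, frame_rate=12.0)
        study = simulate_study(cfg)
        curves = list(study_tics(study, cfg))
        assert len(curves) == len(study)
        for (idx, tic), (_, row) in zip(curves, study.iterrows()):
            assert tic.meta["animal_id"] == row["animal_id"]
            assert tic.meta["timepoint"] == row["timepoint"]

    def test_deterministic_under_seed(self):
        cfg = StudyConfig(n_per_group=2, timepoints=("day0",), seed=3,
                          duration_s=2.0, frame_rate=12.0)
        study = simulate_study(cfg)
        a = [t.intensities for _, t in study_tics(study, cfg)]
        b = [t.intensities for _, t in study_tics(study, cfg)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


def test_end_to_end_recovery_noisy():
    """simulate -> fit -> extract recovers ground-truth PE, AUC and TTP
    with small median error at 2%-of-peak noise."""
    p = BolusModelParams(O=5.0, A=100.0, mu=1.0, sigma=0.5, t0=2.0)
    truths = extract_parameters(FitResult(
        params=p, rss=0.0, converged=True, n_starts=1, time_origin=0.0))
    pe_true, auc_true, ttp_true = truths.pe, truths.auc, truths.ttp
    errs = {"pe": [], "auc": [], "ttp": []}
    for s in range(20):
        tic = simulate_tic(p, noise_sd=0.02 * pe_true, seed=500 + s)
        pp = extract_parameters(fit_bolus_model(tic, FitConfig(seed=s)))
        errs["pe"].append(abs(pp.pe - pe_true) / pe_true)
        errs["auc"].append(abs(pp.auc - auc_true) / auc_true)
        errs["ttp"].append(abs(pp.ttp - ttp_true) / ttp_true)
    for name, vals in errs.items():
        assert np.median(vals) < 0.05, name
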