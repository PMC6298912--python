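"""Synthetic CEUS study generator.

Emulates a two-arm longitudinal mouse-ovary study: a GnRH-analogue
(decapeptyl) arm versus saline controls, imaged at three timepoints
(day 0, 10, 20).  Three levels of realism are provided:

* :func:`simulate_tic` — a single time-intensity curve from known bolus
  parameters on the acquisition grid (55 s at 36 frames/s by default),
  with additive Gaussian noise;
* :func:`simulate_cine` — a cine loop containing an elliptical "ovary"
  whose in-ROI pixels follow a model TIC, over a static speckled
  background, together with the ground-truth ROI mask;
* :func:`simulate_study` — a full per-animal study table whose group
  means and standard deviations reproduce the published two-arm summary
  statistics (B-mode diameters plus the nine CEUS perfusion parameters),
  with per-animal ground-truth bolus parameters back-solved so that the
  model-true peak enhancement equals the drawn measurement.

No acoustic physics is simulated: intensities are treated as already
linearised, and follicle/ovary diameters are drawn, never measured from
images (in the emulated study they are manual B-mode calliper readings).
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roi_tic import CineLoop, RoiMask
from .tic_model import BolusModelParams, TimeIntensityCurve, evaluate_model

__all__ = [
    "TABLE_GROUP_EFFECTS",
    "US_PARAMETERS",
    "CEUS_PARAMETERS",
    "StudyConfig",
    "simulate_tic",
    "simulate_cine",
    "simulate_study",
    "study_tics",
    "back_solve_area",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: B-mode (US) measurements, in mm.
US_PARAMETERS = ("ovary_diameter_mm", "follicle_diameter_mm")
#: CEUS perfusion parameters, in the units of :class:`PerfusionParameters`.
CEUS_PARAMETERS = ("pe", "wir", "ttp", "rt", "auc", "mtt", "pi", "wipi", "wiauc")

#: Published group summaries: parameter -> timepoint -> arm -> (mean, sd).
#: These are the generative defaults of :class:`StudyConfig`.
TABLE_GROUP_EFFECTS: Mapping = {
    "ovary_diameter_mm": {
        "day0": {"decapeptyl": (2.427, 0.70), "control": (2.039, 0.38)},
        "day10": {"decapeptyl": (2.805, 0.66), "control": (2.260, 0.50)},
        "day20": {"decapeptyl": (2.470, 0.77), "control": (2.183, 0.48)},
    },
    "follicle_diameter_mm": {
        "day0": {"decapeptyl": (0.242, 0.07), "control": (0.183, 0.06)},
        "day10": {"decapeptyl": (0.659, 0.07), "control": (0.170, 0.05)},
        "day20": {"decapeptyl": (0.430, 0.13), "control": (0.235, 0.05)},
    },
    "pe": {
        "day0": {"decapeptyl": (80.95, 6.86), "control": (41.8, 9.475)},
        "day10": {"decapeptyl": (87.25, 0.21), "control": (88.60, 57.56)},
        "day20": {"decapeptyl": (117.10, 18.67), "control": (145.0, 12.73)},
    },
    "wir": {
        "day0": {"decapeptyl": (27.83, 15.84), "control": (29.67, 14.00)},
        "day10": {"decapeptyl": (58.87, 48.04), "control": (66.25, 68.94)},
        "day20": {"decapeptyl": (19.09, 10.35), "control": (98.65, 28.78)},
    },
    "ttp": {
        "day0": {"decapeptyl": (5.22, 2.02), "control": (4.07, 1.85)},
        "day10": {"decapeptyl": (9.94, 8.10), "control": (4.04, 2.00)},
        "day20": {"decapeptyl": (4.19, 0.67), "control": (3.04, 0.62)},
    },
    "rt": {
        "day0": {"decapeptyl": (4.27, 1.66), "control": (3.65, 1.58)},
        "day10": {"decapeptyl": (9.125, 7.66), "control": (3.460, 1.39)},
        "day20": {"decapeptyl": (3.45, 0.74), "control": (2.545, 0.49)},
    },
    "auc": {
        "day0": {"decapeptyl": (3145.00, 657.61), "control": (2120.00, 735.39)},
        "day10": {"decapeptyl": (5045.00, 2538.51), "control": (2450.00, 1088.94)},
        "day20": {"decapeptyl": (362.50, 195.87), "control": (4975.00, 473.76)},
    },
    "mtt": {
        "day0": {"decapeptyl": (41.76, 25.51), "control": (59.60, 17.34)},
        "day10": {"decapeptyl": (76.13, 26.51), "control": (27.34, 0.23)},
        "day20": {"decapeptyl": (42.79, 33.60), "control": (55.82, 14.40)},
    },
    "pi": {
        "day0": {"decapeptyl": (86.70, 37.19), "control": (35.30, 1.98)},
        "day10": {"decapeptyl": (64.40, 10.89), "control": (89.35, 39.10)},
        "day20": {"decapeptyl": (14.84, 16.21), "control": (91.20, 15.27)},
    },
    "wipi": {
        "day0": {"decapeptyl": (54.60, 3.82), "control": (29.15, 7.00)},
        "day10": {"decapeptyl": (62.80, 4.24), "control": (62.25, 43.06)},
        "day20": {"decapeptyl": (11.35, 12.23), "control": (97.7, 8.91)},
    },
    "wiauc": {
        "day0": {"decapeptyl": (230.00, 73.54), "control": (100.65, 20.29)},
        "day10": {"decapeptyl": (589.50, 519.72), "control": (185.50, 62.93)},
        "day20": {"decapeptyl": (34.65, 33.87), "control": (246.50, 24.75)},
    },
}


@dataclass(frozen=True)
class StudyConfig:
    """Generative settings for a two-arm study.

    Defaults emulate the published design: 10 animals per arm, three
    timepoints, 55 s wash-in cine loops at 36 frames/s, group effects from
    the published summary table, TIC noise at 2% of the peak enhancement.
    """

    n_per_group: int = 10
    arms: Sequence[str] = ("decapeptyl", "control")
    timepoints: Sequence[str] = ("day0", "day10", "day20")
    group_effects: Mapping = field(default_factory=lambda: TABLE_GROUP_EFFECTS)
    duration_s: float = 55.0
    frame_rate: float = 36.0
    baseline_au: float = 5.0
    tic_noise_frac: float = 0.02  # additive TIC noise sd as a fraction of PE
    speckle_sd: float = 0.10  # multiplicative background speckle sd
    seed: int = 0
    #: template lognormal spread of generated boluses
    sigma: float = 0.5
    #: range of the lognormal scale exp(mu), s (bolus transit timescale)
    mu_scale_range_s: tuple[float, float] = (4.0, 8.0)
    #: range of bolus arrival times, s after acquisition start
    arrival_range_s: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per arm")
        if self.duration_s * self.frame_rate < 8:
            raise ValueError("acquisition must cover at least 8 frames")
        for par, by_tp in self.group_effects.items():
            for tp, by_arm in by_tp.items():
                for arm, (_, sd) in by_arm.items():
                    if sd <= 0:
                        raise ValueError(f"sd must be > 0 ({par}/{tp}/{arm})")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_tic(
    params: BolusModelParams,
    duration: float = 55.0,
    frame_rate: float = 36.0,
    noise_sd: float = 0.0,
    seed=0,
    meta: Mapping | None = None,
) -> TimeIntensityCurve:
    """Sample the bolus model on a uniform acquisition grid plus noise.

    Additive i.i.d. Gaussian noise of standard deviation ``noise_sd``
    (a.u.) is applied and the result clipped at zero; ``noise_sd=0``
    returns the exact model curve.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = int(round(duration * frame_rate))
    times = np.arange(n) / frame_rate
    y = evaluate_model(params, times)
    if noise_sd > 0:
        rng = _as_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, size=n), 0.0, None)
    return TimeIntensityCurve(times=times, intensities=y, meta=dict(meta or {}))


def simulate_cine(
    params: BolusModelParams,
    ovary_diameter_mm: float = 1.8,
    axis_ratio: float = 0.7,
    pixel_size_mm: float = 0.05,
    field_shape: tuple[int, int] = (64, 64),
    duration: float = 55.0,
    frame_rate: float = 36.0,
    background_au: float | None = None,
    speckle_sd: float = 0.10,
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[CineLoop, RoiMask]:
    """Plant an elliptical ovary following a model TIC in a speckled field.

    The ovary is an axis-aligned ellipse centred in the field with major
    diameter ``ovary_diameter_mm`` (murine ovaries run 1-2.5 mm) and minor
    axis ``axis_ratio`` times that.  In-mask pixels carry the model TIC
    value plus independent Gaussian noise per pixel and frame; the
    background is a static multiplicative-speckle texture around the model
    baseline.  Returns the loop and the planted mask.
    """
    rng = _as_rng(seed)
    rows, cols = field_shape
    a_px = 0.5 * ovary_diameter_mm / pixel_size_mm        # major semi-axis, cols
    b_px = 0.5 * ovary_diameter_mm * axis_ratio / pixel_size_mm
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    if a_px > c0 or b_px > r0:
        raise ValueError("ovary ellipse does not fit in the field of view")

    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = ((cc - c0) / a_px) ** 2 + ((rr - r0) / b_px) ** 2 <= 1.0
    roi = RoiMask(mask=mask)

    n = int(round(duration * frame_rate))
    times = np.arange(n) / frame_rate
    tic = evaluate_model(params, times)

    bg_level = params.O if background_au is None else background_au
    background = bg_level * (1.0 + speckle_sd * rng.standard_normal((rows, cols)))
    background = np.clip(background, 0.0, None)

    frames = np.broadcast_to(background, (n, rows, cols)).copy()
    npx = roi.n_pixels
    inside = tic[:, None] * np.ones((1, npx))
    if noise_sd > 0:
        inside = inside + rng.normal(0.0, noise_sd, size=inside.shape)
    frames[:, mask] = np.clip(inside, 0.0, None)

    cine = CineLoop(frames=frames, frame_interval=1.0 / frame_rate,
                    pixel_size=pixel_size_mm,
                    meta={"ovary_diameter_mm": ovary_diameter_mm})
    return cine, roi


def back_solve_area(pe: float, mu: float, sigma: float) -> float:
    """Bolus area A whose lognormal peak enhancement equals ``pe``.

    Inverts PE = A * exp(sigma^2/2 - mu) / (sigma * sqrt(2*pi)).
    """
    if pe < 0:
        raise ValueError("peak enhancement must be non-negative")
    return pe * sigma * _SQRT_2PI * math.exp(mu - sigma ** 2 / 2.0)


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   max_tries: int = 100) -> float:
    """Normal draw truncated at zero by rejection."""
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError(
        f"could not draw a positive value from N({mean}, {sd}) "
        f"in {max_tries} tries"
    )


def simulate_study(config: StudyConfig | None = None) -> pd.DataFrame:
    """Generate a per-animal study table with the configured group effects.

    One row per arm x timepoint x animal.  Measurement columns (the US
    diameters and nine CEUS parameters) are independent truncated-normal
    draws from the configured per-group distributions.  Each row also
    carries ground-truth bolus model parameters (``true_*`` columns)
    back-solved so the model-true peak enhancement equals the drawn ``pe``
    measurement; :func:`study_tics` turns them into curves.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    lo_s, hi_s = config.mu_scale_range_s
    lo_t0, hi_t0 = config.arrival_range_s

    rows = []
    for tp in config.timepoints:
        for arm in config.arms:
            for animal in range(config.n_per_group):
                row: dict = {
                    "arm": arm,
                    "timepoint": tp,
                    "animal_id": f"{arm}-{animal:02d}",
                }
                for par, by_tp in config.group_effects.items():
                    mean, sd = by_tp[tp][arm]
                    row[par] = _draw_positive(rng, mean, sd)
                mu = math.log(rng.uniform(lo_s, hi_s))
                t0 = rng.uniform(lo_t0, hi_t0)
                sigma = config.sigma
                pe = row.get("pe", 1.0)
                A = back_solve_area(pe, mu, sigma)
                row.update(
                    true_O=config.baseline_au, true_A=A, true_mu=mu,
                    true_sigma=sigma, true_t0=t0, true_pe=pe, true_auc=A,
                    true_ttp=t0 + math.exp(mu - sigma ** 2),
                    true_mtt=math.exp(mu + sigma ** 2 / 2.0),
                )
                rows.append(row)
    return pd.DataFrame(rows)


def study_tics(study: pd.DataFrame, config: StudyConfig | None = None):
    """Yield ``(row_index, TimeIntensityCurve)`` for each study row.

    Curves are generated from the row's ground-truth parameters on the
    configured acquisition grid, with additive noise at
    ``tic_noise_frac`` of the row's true peak enhancement.  Per-row noise
    seeds are derived deterministically from the study seed.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    for idx, row in study.iterrows():
        params = BolusModelParams(O=row["true_O"], A=row["true_A"],
                                  mu=row["true_mu"], sigma=row["true_sigma"],
                                  t0=row["true_t0"])
        tic = simulate_tic(
            params,
            duration=config.duration_s,
            frame_rate=config.frame_rate,
            noise_sd=config.tic_noise_frac * row["true_pe"],
            seed=rng,
            meta={"animal_id": row["animal_id"], "arm": row["arm"],
                  "timepoint": row["timepoint"]},
        )
        yield idx, tic
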