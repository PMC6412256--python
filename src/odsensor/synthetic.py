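"""Synthetic measurement campaigns with ground truth.

No image set ships with this package, so every stage of the sensor is
exercised against generated fixtures that reproduce the structure the
pipeline assumes: a batch of experiments, half-hourly timepoints, four
replicate frames per timepoint, two acquisition backdrops with different
contrast, a medium colour drifting monotonically with optical density,
global illumination jitter moving whole-image reference means, and a
dilution step in the OD readings above 0.7.

Two response modes exist.  ``growth`` records OD from an exponential
growth law and colours the medium through a saturating log law calibrated
against a representative measured trajectory (:func:`reference_trajectory`);
this is the realistic default.  ``linear`` instead defines the recorded OD
exactly through the regression model from known coefficients, so that a
noise-free campaign is perfectly identifiable — the oracle used by the
recovery and cross-validation tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import features
from .colourspace import LabTriple, lab_to_rgb, write_mask

__all__ = [
    "GrowthParams",
    "ColourCoeffs",
    "CampaignSpec",
    "Campaign",
    "generate_od_trajectory",
    "od_to_lab",
    "render_scene",
    "generate_campaign",
    "generate_ground_truth",
    "reference_trajectory",
    "DEFAULT_LINEAR_BETA",
]

log = logging.getLogger(__name__)

# Representative measured trajectory of one cultivation (whole-image
# reference colour, region-of-interest colour and OD every 30 min); the
# generator defaults below are calibrated so its endpoints are reproduced.
_REFERENCE_ROWS = [
    # time_h, Lref, aref, bref, L, a, b, OD
    (0.0, 57.18, 2.81, 12.78, 28.25, 14.18, 28.82, 0.00),
    (0.5, 54.04, 4.39, 14.09, 26.83, 14.46, 27.55, 0.01),
    (1.0, 53.00, 3.71, 15.33, 27.37, 14.15, 26.75, 0.02),
    (1.5, 54.35, 5.14, 16.27, 28.52, 15.30, 29.13, 0.03),
    (2.0, 52.92, 4.49, 15.90, 25.93, 14.44, 28.42, 0.04),
    (2.5, 53.38, 3.71, 16.07, 24.81, 14.90, 28.06, 0.05),
    (3.0, 55.08, 2.49, 15.50, 27.21, 13.60, 28.92, 0.06),
    (3.5, 54.51, 3.63, 15.52, 26.50, 14.37, 27.56, 0.08),
    (4.0, 56.08, 2.61, 15.78, 28.97, 13.12, 28.35, 0.13),
    (4.5, 56.96, 3.47, 14.76, 28.14, 13.28, 28.61, 0.15),
    (5.0, 56.49, 3.19, 15.48, 29.88, 12.16, 28.90, 0.89),
    (5.5, 55.86, 1.71, 13.02, 28.98, 10.47, 29.39, 0.40),
    (6.0, 58.23, 1.38, 15.12, 32.38, 9.00, 30.09, 0.59),
    (6.5, 57.56, 1.97, 16.99, 32.73, 10.50, 32.23, 0.64),
    (7.0, 56.13, 2.36, 16.32, 34.49, 9.28, 33.16, 1.10),
    (7.5, 56.23, 0.24, 13.41, 35.22, 6.19, 32.16, 1.88),
    (8.0, 58.41, 0.77, 17.27, 38.79, 7.18, 35.62, 2.83),
    (8.5, 56.47, 2.21, 16.30, 38.83, 6.00, 33.98, 4.09),
    (9.0, 56.32, 1.74, 15.46, 40.24, 5.50, 32.35, 5.66),
    (9.5, 58.49, 1.04, 16.27, 44.93, 5.16, 35.66, 7.18),
]

# Acquisition backdrop per experiment in the emulated campaign (1 = white
# tabletop, poor contrast; 2 = blue floor spot, good contrast).
_LOCATION_PATTERN = (1, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 2)
_INOCULUM_PATTERN = (15, 15, 15) + (10,) * 15

DEFAULT_LINEAR_BETA = (0.4, 2.5, -1.8, 1.2, -0.9, 0.7, -0.5, 0.8, -0.3, 0.4)

# seed-stream tags so independent noise sources never share a generator
_STREAM_OD, _STREAM_ILLUM, _STREAM_FRAME, _STREAM_BASE, _STREAM_GROWTH = range(5)


def reference_trajectory() -> pd.DataFrame:
    """The calibration trajectory as a colour-summary table."""
    return pd.DataFrame(_REFERENCE_ROWS, columns=features.SUMMARY_COLUMNS)


@dataclass(frozen=True)
class GrowthParams:
    """Exponential growth after a lag: OD(t) = od0 * exp(mu * max(0, t-lag))."""

    od0: float = 0.01
    mu: float = 0.7318     # 1/h; brings od0 at 0.5 h to ~7.2 at 9.5 h
    lag: float = 0.5


@dataclass(frozen=True)
class ColourCoeffs:
    """Medium colour as a saturating function of OD.

    With s = ln(1 + k * od): L = L0 + Lg*s, a = a0 + ag*s, b = b0 + bg*s.
    Defaults interpolate the calibration trajectory's endpoints: colour
    (26.8, 14.5, 27.5) at vanishing OD and roughly (44.9, 5.2, 35.8) at
    OD 7.18; L and b increase with OD while a decreases.
    """

    L0: float = 26.8
    Lg: float = 7.0
    a0: float = 14.5
    ag: float = -3.6
    b0: float = 27.5
    bg: float = 3.2
    k: float = 1.7


def default_timepoints() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 9.51, 0.5), 1))


@dataclass(frozen=True)
class CampaignSpec:
    """Everything needed to deterministically regenerate a campaign."""

    n_experiments: int = 18
    timepoints: tuple[float, ...] = field(default_factory=default_timepoints)
    frames_per_timepoint: int = 4
    image_size: tuple[int, int] = (256, 341)   # (H, W)
    locations: tuple[int, ...] | None = None
    inoculum_ml: tuple[float, ...] | None = None
    growth: GrowthParams = field(default_factory=GrowthParams)
    colour: ColourCoeffs = field(default_factory=ColourCoeffs)
    pixel_sigma: float = 0.8        # per-pixel Lab noise
    illum_sigma: float = 1.0        # per-timepoint global lightness offset
    frame_jitter_sigma: float = 0.3  # extra per-frame lightness jitter
    od_cv: float = 0.04             # multiplicative photometer noise
    od_read_sigma: float = 0.002    # additive absorbance reading noise
    baseline_spread: float = 0.5    # per-experiment medium base-colour jitter
    growth_spread: float = 0.05     # relative jitter on mu and od0
    response_mode: str = "growth"   # "growth" | "linear"
    beta: tuple[float, ...] = DEFAULT_LINEAR_BETA
    linear_response_sigma: float = 0.0  # log-OD noise in linear mode
    inject_outlier: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")
        if self.response_mode not in ("growth", "linear"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")
        for name in ("pixel_sigma", "illum_sigma", "frame_jitter_sigma",
                     "od_cv", "od_read_sigma", "baseline_spread", "growth_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def location_of(self, exp_idx: int) -> int:
        if self.locations is not None:
            return self.locations[exp_idx]
        if exp_idx < len(_LOCATION_PATTERN):
            return _LOCATION_PATTERN[exp_idx]
        return 1 + (exp_idx % 2)

    def inoculum_of(self, exp_idx: int) -> float:
        if self.inoculum_ml is not None:
            return self.inoculum_ml[exp_idx]
        if exp_idx < len(_INOCULUM_PATTERN):
            return _INOCULUM_PATTERN[exp_idx]
        return 10.0

    def experiment_ids(self) -> list[str]:
        return [f"exp{i + 1:02d}" for i in range(self.n_experiments)]

    def noiseless(self) -> "CampaignSpec":
        """Copy of the spec with every noise source set to zero."""
        return replace(
            self, pixel_sigma=0.0, illum_sigma=0.0, frame_jitter_sigma=0.0,
            od_cv=0.0, od_read_sigma=0.0, baseline_spread=0.0,
            growth_spread=0.0, linear_response_sigma=0.0, inject_outlier=False,
        )


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


# --------------------------------------------------------------------------
# growth and colour models

_DILUTION_STEPS = (2, 5, 10, 20, 50, 100, 200, 500, 1000)
_DILUTION_THRESHOLD = 0.7


def generate_od_trajectory(
    timepoints,
    growth: GrowthParams,
    rng: np.random.Generator | None = None,
    od_cv: float = 0.0,
    od_read_sigma: float = 0.0,
) -> pd.DataFrame:
    """True and recorded OD per timepoint.

    OD at t = 0 is zero by definition (the photometer is blanked on the
    fresh medium).  Recorded values carry multiplicative lognormal noise
    plus additive reading noise; above an absorbance of 0.7 the sample is
    diluted to a readable range and the reading scaled back, so the
    additive noise is amplified by the dilution factor and late readings
    are realistically noisier.
    """
    if growth.mu <= 0:
        raise ValueError("growth rate mu must be positive")
    rng = rng or _rng(0)
    rows = []
    for t in timepoints:
        if t == 0.0:
            rows.append({"time_h": 0.0, "od_true": 0.0, "od_recorded": 0.0,
                         "dilution": 1})
            continue
        od = growth.od0 * math.exp(growth.mu * max(0.0, t - growth.lag))
        mult = math.exp(rng.normal(0.0, od_cv)) if od_cv > 0 else 1.0
        dilution = 1
        if od > _DILUTION_THRESHOLD:
            for d in _DILUTION_STEPS:
                if od / d <= 0.5:
                    dilution = d
                    break
            else:
                dilution = _DILUTION_STEPS[-1]
        reading = (od / dilution) * mult + rng.normal(0.0, od_read_sigma)
        recorded = max(reading * dilution, 1e-3)
        rows.append({"time_h": t, "od_true": od, "od_recorded": recorded,
                     "dilution": dilution})
    return pd.DataFrame(rows)


def od_to_lab(od: float, coeffs: ColourCoeffs = ColourCoeffs()) -> LabTriple:
    """Medium colour for a given optical density (monotone in OD)."""
    if od < 0:
        raise ValueError("optical density cannot be negative")
    s = math.log1p(coeffs.k * od)
    L = coeffs.L0 + coeffs.Lg * s
    a = coeffs.a0 + coeffs.ag * s
    b = coeffs.b0 + coeffs.bg * s
    if not (0.0 < L < 100.0):
        log.warning("colour coefficients push L to %.1f, outside plausible range", L)
    return LabTriple(L, a, b)


# --------------------------------------------------------------------------
# scene renderer

# flat Lab palette per backdrop; region order:
# background, bench, flask body, neck, cap, label
# Chromas are kept moderate so the whole-image mean stays positive in a and
# b (the plain log transform of the reference colour must be defined).
_PALETTES = {
    1: {  # white tabletop: warm wooden bench sits close to the medium colours
        "background": (88.0, 1.0, 8.0),
        "bench": (48.0, 9.0, 20.0),
        "body": (65.0, -1.0, 10.0),
        "neck": (60.0, -1.0, 14.0),
        "cap": (52.0, 5.0, -25.0),
        "label": (78.0, 12.0, 18.0),
    },
    2: {  # blue floor spot: every region far (Euclidean Lab) from the medium
        "background": (35.0, 8.0, -4.0),
        "bench": (28.0, 5.0, -12.0),
        "body": (62.0, -4.0, 0.0),
        "neck": (57.0, -3.0, 4.0),
        "cap": (78.0, 2.0, -6.0),
        "label": (82.0, 4.0, 22.0),
    },
}

# Total L swing across the backdrop, top to bottom.  Deliberately large:
# the background then soaks up the surplus clusters of a generous K instead
# of the flat medium region being split.
_BG_GRADIENT_SPAN = 16.0

_scene_cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _scene_base(location: int, size: tuple[int, int]):
    """(base Lab image without medium, medium mask, region id map), cached."""
    key = (location, size)
    if key in _scene_cache:
        return _scene_cache[key]
    h, w = size
    if h < 8 or w < 8:
        raise ValueError(f"degenerate image size {size}")
    pal = _PALETTES[location]
    yy, xx = np.mgrid[0:h, 0:w]
    region = np.zeros((h, w), dtype=np.uint8)  # 0 background

    region[yy >= int(0.92 * h)] = 1                                   # bench
    body = ((yy - 0.62 * h) / (0.30 * h)) ** 2 + ((xx - 0.5 * w) / (0.32 * w)) ** 2 <= 1.0
    region[body] = 2
    neck = (yy >= 0.15 * h) & (yy < 0.35 * h) & (xx >= 0.44 * w) & (xx < 0.56 * w)
    region[neck] = 3
    cap = (yy >= 0.08 * h) & (yy < 0.16 * h) & (xx >= 0.42 * w) & (xx < 0.58 * w)
    region[cap] = 4
    label = (yy >= 0.40 * h) & (yy < 0.50 * h) & (xx >= 0.40 * w) & (xx < 0.60 * w)
    region[label] = 5
    medium = ((yy - 0.70 * h) / (0.18 * h)) ** 2 + ((xx - 0.5 * w) / (0.26 * w)) ** 2 <= 1.0
    medium &= body  # liquid cannot poke outside the flask
    region[medium] = 6

    base = np.empty((h, w, 3))
    names = ["background", "bench", "body", "neck", "cap", "label"]
    for idx, name in enumerate(names):
        base[region == idx] = pal[name]
    # smooth vertical lightness gradient on the backdrop only; gives the
    # background internal structure so surplus clusters are absorbed there
    grad = _BG_GRADIENT_SPAN * (yy / max(h - 1, 1) - 0.5)
    backdrop = region <= 1
    base[..., 0][backdrop] += grad[backdrop]
    base[region == 6] = 0.0  # filled per frame

    _scene_cache[key] = (base, medium, region)
    return _scene_cache[key]


def _scene_reference(medium_lab, location: int, size: tuple[int, int]) -> np.ndarray:
    """Whole-image mean Lab of the noiseless, offset-free scene."""
    base, mask, _ = _scene_base(location, size)
    n = base.shape[0] * base.shape[1]
    n_med = int(mask.sum())
    fixed = base.reshape(-1, 3).sum(axis=0)  # medium pixels are zeroed in base
    return (fixed + n_med * np.asarray(medium_lab, dtype=float)) / n


def render_scene(
    medium_lab,
    location: int,
    illumination_offset: float = 0.0,
    rng: np.random.Generator | None = None,
    size: tuple[int, int] = (256, 341),
    pixel_sigma: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one frame: sRGB image, medium mask, and ground-truth info.

    The scene is deliberately schematic — flat colour-separable regions
    plus noise — because colour separability is the property the pipeline
    relies on, not photorealism.  The illumination offset shifts the
    lightness of every pixel, medium included, which is what makes the
    whole-image reference colour informative.
    """
    if location not in _PALETTES:
        raise ValueError(f"unknown location {location}; expected 1 or 2")
    base, mask, _ = _scene_base(location, size)
    lab = base.copy()
    lab[mask] = np.asarray(medium_lab, dtype=float)
    truth_medium = np.asarray(medium_lab, dtype=float) + [illumination_offset, 0.0, 0.0]
    lab[..., 0] += illumination_offset
    truth_reference = lab.reshape(-1, 3).mean(axis=0)
    if pixel_sigma > 0:
        if rng is None:
            raise ValueError("pixel noise requested but no rng supplied")
        lab = lab + rng.normal(0.0, pixel_sigma, size=lab.shape)
    rgb = lab_to_rgb(lab)
    info = {
        "medium_lab": LabTriple(*map(float, truth_medium)),
        "reference_lab": LabTriple(*map(float, truth_reference)),
        "location": location,
        "illumination_offset": float(illumination_offset),
    }
    return rgb, mask, info


# --------------------------------------------------------------------------
# campaign assembly


@dataclass(frozen=True)
class _ExperimentParams:
    colour: ColourCoeffs
    growth: GrowthParams
    location: int
    inoculum_ml: float


class Campaign:
    """A deterministic, lazily rendered measurement campaign.

    The colour/OD ground truth for all experiments is computed on
    construction (cheap); frames are rendered on demand from seeds derived
    from the master seed, so two campaigns with equal specs are
    bit-identical without holding 1400+ images in memory.
    """

    def __init__(self, spec: CampaignSpec):
        self.spec = spec
        self._params: list[_ExperimentParams] = []
        for e in range(spec.n_experiments):
            rng_b = _rng(spec.seed, e, _STREAM_BASE)
            colour = replace(
                spec.colour,
                L0=spec.colour.L0 + rng_b.normal(0, spec.baseline_spread),
                a0=spec.colour.a0 + rng_b.normal(0, spec.baseline_spread),
                b0=spec.colour.b0 + rng_b.normal(0, spec.baseline_spread),
            )
            rng_g = _rng(spec.seed, e, _STREAM_GROWTH)
            growth = replace(
                spec.growth,
                mu=spec.growth.mu * (1 + rng_g.normal(0, spec.growth_spread)),
                od0=spec.growth.od0 * (1 + rng_g.normal(0, spec.growth_spread)),
            )
            self._params.append(
                _ExperimentParams(colour, growth, spec.location_of(e), spec.inoculum_of(e))
            )
        self.truth = self._build_truth()

    # -- ground truth ------------------------------------------------------

    def _frame_offsets(self, e: int, t_idx: int) -> np.ndarray:
        spec = self.spec
        base = _rng(spec.seed, e, t_idx, _STREAM_ILLUM).normal(0, spec.illum_sigma) \
            if spec.illum_sigma > 0 else 0.0
        jitters = np.array([
            _rng(spec.seed, e, t_idx, j, _STREAM_FRAME).normal(0, spec.frame_jitter_sigma)
            if spec.frame_jitter_sigma > 0 else 0.0
            for j in range(spec.frames_per_timepoint)
        ])
        return base + jitters

    def _build_truth(self) -> pd.DataFrame:
        spec = self.spec
        recs = []
        for e, params in enumerate(self._params):
            traj = generate_od_trajectory(
                spec.timepoints, params.growth,
                rng=_rng(spec.seed, e, _STREAM_OD),
                od_cv=spec.od_cv, od_read_sigma=spec.od_read_sigma,
            )
            for t_idx, row in traj.iterrows():
                medium = od_to_lab(row.od_true, params.colour).as_array()
                offsets = self._frame_offsets(e, t_idx)
                mean_off = float(np.mean(offsets))
                ref = _scene_reference(medium, params.location, spec.image_size)
                ref = ref + [mean_off, 0.0, 0.0]
                roi = medium + [mean_off, 0.0, 0.0]
                recs.append({
                    "experiment_id": f"exp{e + 1:02d}",
                    "location": params.location,
                    "inoculum_ml": params.inoculum_ml,
                    "time_h": float(row.time_h),
                    "od_true": float(row.od_true),
                    "OD": float(row.od_recorded),
                    "L": roi[0], "a": roi[1], "b": roi[2],
                    "Lref": ref[0], "aref": ref[1], "bref": ref[2],
                    "medium_L": medium[0], "medium_a": medium[1], "medium_b": medium[2],
                    "mean_offset": mean_off,
                })
        truth = pd.DataFrame(recs)
        if spec.response_mode == "linear":
            truth = self._apply_linear_response(truth)
        if spec.inject_outlier:
            rng = _rng(spec.seed, 10_000)
            i = truth.index[(truth.time_h > 2.0) & (truth.time_h < 8.0)]
            pick = rng.choice(i)
            truth.loc[pick, "OD"] *= float(rng.uniform(3.0, 8.0))
            log.info("injected OD outlier at row %d", pick)
        return truth

    def _apply_linear_response(self, truth: pd.DataFrame) -> pd.DataFrame:
        """Overwrite recorded OD so log OD is exactly linear in the predictors."""
        spec = self.spec
        beta = np.asarray(spec.beta, dtype=float)
        if beta.shape != (10,):
            raise ValueError("linear response needs 10 coefficients (intercept first)")
        meas = [
            features.Measurement(
                experiment_id=r.experiment_id, timepoint=r.time_h,
                roi=LabTriple(r.L, r.a, r.b),
                reference=LabTriple(r.Lref, r.aref, r.bref),
                od=1.0,  # placeholder; only predictors are needed here
            )
            for r in truth.itertuples(index=False)
        ]
        design = features.build_design_matrix(meas, drop_t0=True)
        X = design[features.DESIGN_COLUMNS].to_numpy()
        log_od = np.column_stack([np.ones(len(X)), X]) @ beta
        if spec.linear_response_sigma > 0:
            log_od = log_od + _rng(spec.seed, 20_000).normal(
                0, spec.linear_response_sigma, size=log_od.shape
            )
        key = dict(zip(zip(design.experiment_id, design.time_h), np.exp(log_od)))
        od = [
            0.0 if r.time_h == 0.0 else key[(r.experiment_id, r.time_h)]
            for r in truth.itertuples(index=False)
        ]
        truth = truth.copy()
        truth["OD"] = od
        return truth

    # -- views -------------------------------------------------------------

    def experiment_ids(self) -> list[str]:
        return self.spec.experiment_ids()

    def summary_truth(self) -> pd.DataFrame:
        """Colour-summary table computed from ground truth (no segmentation)."""
        cols = ["experiment_id"] + features.SUMMARY_COLUMNS
        return self.truth[cols].copy()

    def frames(self, exp_idx: int, t_idx: int):
        """Render the replicate frames of one timepoint: list of (rgb, mask, info)."""
        spec = self.spec
        params = self._params[exp_idx]
        row = self.truth[
            (self.truth.experiment_id == f"exp{exp_idx + 1:02d}")
            & (self.truth.time_h == spec.timepoints[t_idx])
        ].iloc[0]
        medium = np.array([row.medium_L, row.medium_a, row.medium_b])
        offsets = self._frame_offsets(exp_idx, t_idx)
        out = []
        for j in range(spec.frames_per_timepoint):
            rng = _rng(spec.seed, exp_idx, t_idx, j, _STREAM_FRAME + 10)
            out.append(
                render_scene(
                    medium, params.location, illumination_offset=float(offsets[j]),
                    rng=rng, size=spec.image_size, pixel_sigma=spec.pixel_sigma,
                )
            )
        return out

    # -- persistence -------------------------------------------------------

    def write(self, outdir) -> Path:
        """Write images, masks, manifest and ground truth as plain artefacts."""
        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "masks").mkdir(exist_ok=True)
        manifest = []
        for e in range(self.spec.n_experiments):
            eid = f"exp{e + 1:02d}"
            for t_idx, t in enumerate(self.spec.timepoints):
                for j, (rgb, mask, info) in enumerate(self.frames(e, t_idx)):
                    name = f"{eid}_t{t_idx:02d}_f{j}.png"
                    img8 = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
                    Image.fromarray(img8).save(outdir / "images" / name)
                    if j == 0:
                        write_mask(outdir / "masks" / f"{eid}_t{t_idx:02d}.png", mask)
                    manifest.append({
                        "experiment_id": eid,
                        "location": info["location"],
                        "inoculum_ml": self._params[e].inoculum_ml,
                        "time_h": t,
                        "frame": j,
                        "image_path": f"images/{name}",
                    })
        pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
        features.write_colour_summary(self.summary_truth(), outdir / "summary_truth.csv")
        self.truth.to_csv(outdir / "ground_truth.csv", index=False)
        with open(outdir / "spec.json", "w") as fh:
            json.dump(self._spec_dict(), fh, indent=2, default=str)
        return outdir

    def _spec_dict(self) -> dict:
        d = {k: getattr(self.spec, k) for k in (
            "n_experiments", "frames_per_timepoint", "image_size", "seed",
            "pixel_sigma", "illum_sigma", "frame_jitter_sigma", "od_cv",
            "od_read_sigma", "baseline_spread", "growth_spread",
            "response_mode", "inject_outlier",
        )}
        d["timepoints"] = list(self.spec.timepoints)
        return d


def generate_campaign(spec: CampaignSpec | None = None, **overrides) -> Campaign:
    """Build a campaign; keyword overrides patch the default spec."""
    if spec is None:
        spec = CampaignSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    return Campaign(spec)


def generate_ground_truth(spec: CampaignSpec | None = None, **overrides) -> pd.DataFrame:
    """Ground-truth colour summary without rendering any frame."""
    return generate_campaign(spec, **overrides).summary_truth()
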