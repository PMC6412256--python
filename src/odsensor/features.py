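"""Per-measurement colour summaries and the regression design matrix.

Each measurement carries the tracked region colour (L, a, b), the
whole-image reference colour (Lref, aref, bref) and, during training, the
measured optical density.  The design matrix applies a log transform
elementwise and augments every row with the experiment's baseline region
colour (its first retained measurement, absorbing medium differences
between experiments) and the row's own reference colour (absorbing
changing light conditions):

    x1..x3 = log of the row's region colour
    x4..x6 = log of the experiment's baseline region colour
    x7..x9 = log of the row's whole-image reference colour
    response = log OD

The t = 0 h row of each experiment is dropped by default: OD is zero there
by blank definition and cannot be log-transformed, so t = 0.5 h becomes
the first (baseline) measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .colourspace import LabTriple, mean_lab

__all__ = [
    "Measurement",
    "summarize_timepoint",
    "build_design_matrix",
    "read_colour_summary",
    "write_colour_summary",
    "measurements_from_summary",
    "DESIGN_COLUMNS",
    "SUMMARY_COLUMNS",
]

DESIGN_COLUMNS = [f"x{i}" for i in range(1, 10)]
SUMMARY_COLUMNS = ["time_h", "Lref", "aref", "bref", "L", "a", "b", "OD"]


@dataclass(frozen=True)
class Measurement:
    """One timepoint of one experiment, averaged over its replicate frames."""

    experiment_id: str
    timepoint: float
    roi: LabTriple
    reference: LabTriple
    od: float | None = None


def summarize_timepoint(
    frames: Sequence[np.ndarray],
    roi_centres: Sequence[LabTriple | Sequence[float]],
) -> tuple[LabTriple, LabTriple]:
    """Collapse one timepoint's frames to (region colour, reference colour).

    The region colour is the mean of the matched cluster centres, the
    reference the mean over frames of each frame's whole-image mean.
    """
    if len(frames) == 0 or len(roi_centres) == 0:
        raise ValueError("at least one frame and one region centre are required")
    if len(frames) != len(roi_centres):
        raise ValueError("frames and roi_centres must have equal length")
    roi = np.mean([np.asarray(c, dtype=float) for c in roi_centres], axis=0)
    refs = np.mean([mean_lab(f).as_array() for f in frames], axis=0)
    return LabTriple(*map(float, roi)), LabTriple(*map(float, refs))


def _safe_log(value: float, channel: str, exp_id: str, t: float, offset: float) -> float:
    shifted = value + offset
    if not shifted > 0:
        raise ValueError(
            f"cannot log-transform {channel}={value!r} "
            f"(experiment {exp_id!r}, t={t} h); "
            "set log_offset to shift non-positive channels"
        )
    return math.log(shifted)


def build_design_matrix(
    measurements: Iterable[Measurement],
    drop_t0: bool = True,
    log_offset: float = 0.0,
) -> pd.DataFrame:
    """Build the transformed predictor matrix from grouped measurements.

    Returns a frame with columns ``experiment_id``, ``time_h``, ``x1``..``x9``
    and ``response`` (NaN where OD is unknown).  ``log_offset`` is an
    optional shift c0 applied inside the log, ``log(v + c0)``, for data
    whose a/b channels cross zero; it defaults to 0 (plain natural log) and
    a non-positive shifted value is a hard error naming the channel and row.
    """
    by_exp: dict[str, list[Measurement]] = {}
    for m in measurements:
        by_exp.setdefault(m.experiment_id, []).append(m)

    rows = []
    for exp_id, group in by_exp.items():
        group = sorted(group, key=lambda m: m.timepoint)
        retained = [m for m in group if not (drop_t0 and m.timepoint == 0.0)]
        if not retained:
            raise ValueError(f"experiment {exp_id!r} has no retained measurements")
        base = retained[0]
        base_x = [
            _safe_log(v, ch, exp_id, base.timepoint, log_offset)
            for ch, v in zip(("L", "a", "b"), base.roi)
        ]
        for m in retained:
            roi_x = [
                _safe_log(v, ch, exp_id, m.timepoint, log_offset)
                for ch, v in zip(("L", "a", "b"), m.roi)
            ]
            ref_x = [
                _safe_log(v, ch, exp_id, m.timepoint, log_offset)
                for ch, v in zip(("Lref", "aref", "bref"), m.reference)
            ]
            if m.od is None:
                response = np.nan
            else:
                response = _safe_log(m.od, "OD", exp_id, m.timepoint, 0.0)
            rows.append(
                {
                    "experiment_id": exp_id,
                    "time_h": m.timepoint,
                    **dict(zip(DESIGN_COLUMNS, roi_x + base_x + ref_x)),
                    "response": response,
                }
            )
    df = pd.DataFrame(rows)
    if not np.isfinite(df[DESIGN_COLUMNS].to_numpy()).all():
        raise ValueError("non-finite predictor produced by the log transform")
    return df


def measurements_from_summary(summary: pd.DataFrame) -> list[Measurement]:
    """Convert a colour-summary table into :class:`Measurement` objects.

    The table layout is ``time_h, Lref, aref, bref, L, a, b, OD`` with an
    optional leading ``experiment_id`` column (a single unnamed experiment
    is assumed when absent).
    """
    df = summary.copy()
    if "experiment_id" not in df.columns:
        df.insert(0, "experiment_id", "exp1")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"colour summary is missing columns {missing}")
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            Measurement(
                experiment_id=str(rec.experiment_id),
                timepoint=float(rec.time_h),
                roi=LabTriple(float(rec.L), float(rec.a), float(rec.b)),
                reference=LabTriple(float(rec.Lref), float(rec.aref), float(rec.bref)),
                od=None if pd.isna(rec.OD) else float(rec.OD),
            )
        )
    return out


def read_colour_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing colour-summary columns {missing}")
    return df


def write_colour_summary(df: pd.DataFrame, path) -> None:
    cols = (["experiment_id"] if "experiment_id" in df.columns else []) + SUMMARY_COLUMNS
    df.loc[:, cols].to_csv(path, index=False)
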