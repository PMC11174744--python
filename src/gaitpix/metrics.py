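"""Evaluation statistics: absolute/relative error and RMSE between streams.

Two denominator conventions exist for the relative error because validation
tables in this domain mix them: dividing by the ground-truth value (tape
measure, floor marks, manual step count) or by the reference system's
reading (the MEMS-IMU value).  Both are first-class here.

RMSE and RMSD are treated as synonyms: the root mean square of pointwise
differences after aligning the two series on a common timebase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .calibration import round_report
from .errors import AlignmentError, ParameterError
from .kinematics import JointAngleSeries, resample_to
from .landmark_io import ReferenceAngleSeries

DENOMINATORS = ("ground_truth", "reference_system")


@dataclass(frozen=True)
class ErrorReport:
    measured: float
    reference: float
    absolute_error: float
    relative_error_pct: float
    denominator: str


@dataclass(frozen=True)
class SeriesComparison:
    rmse: float
    n_points: int
    alignment: str


def absolute_error(measured: float, reference: float) -> float:
    """|measured − reference|, in the shared units of the inputs."""
    return abs(float(measured) - float(reference))


def relative_error(
    measured: float, reference: float, denom: str = "ground_truth"
) -> float:
    """Percent error with an explicit denominator convention.

    ``ground_truth`` divides by ``reference`` (the trusted external value);
    ``reference_system`` also divides by ``reference`` but is kept as a
    distinct label so reports record which convention produced the number —
    callers pass the appropriate value (tape/manual count vs instrument
    reading) as ``reference``.
    """
    if denom not in DENOMINATORS:
        raise ParameterError(f"denom must be one of {DENOMINATORS}, got {denom!r}")
    reference = float(reference)
    if reference == 0:
        raise ParameterError("relative error undefined: zero denominator")
    return absolute_error(measured, reference) / abs(reference) * 100.0


AngleSeries = Union[JointAngleSeries, ReferenceAngleSeries]


def rmse(
    series_a: AngleSeries,
    series_b: AngleSeries,
    align: str = "linear",
    max_lag_s: float = 1.0,
) -> SeriesComparison:
    """RMSE between two angle streams on series_a's timebase.

    ``align='linear'`` resamples series_b onto series_a's timestamps by
    linear interpolation; ``align='xcorr'`` additionally searches a time lag
    (within ±max_lag_s) minimizing the RMSE before comparing.  Only points
    valid in both series enter the mean.
    """
    if align not in ("linear", "xcorr"):
        raise ParameterError(f"unknown alignment policy {align!r}")
    ta, tb = series_a.timestamps, series_b.timestamps
    if len(ta) == 0 or len(tb) == 0:
        raise AlignmentError("cannot compare empty series")

    def _rmse_at_lag(lag: float) -> tuple[float, int]:
        lo, hi = max(ta[0], tb[0] + lag), min(ta[-1], tb[-1] + lag)
        mask = (ta >= lo) & (ta <= hi)
        if not mask.any():
            return np.nan, 0
        shifted = ReferenceAngleSeries(
            timestamps=tb + lag,
            angles=series_b.angles,
            joint=getattr(series_b, "joint", "knee"),
        )
        resampled = resample_to(shifted, ta[mask])
        a = np.asarray(series_a.angles)[mask]
        b = resampled.angles
        valid = np.isfinite(a) & np.isfinite(b)
        if not valid.any():
            return np.nan, 0
        return float(np.sqrt(np.mean((a[valid] - b[valid]) ** 2))), int(valid.sum())

    if align == "linear":
        value, n = _rmse_at_lag(0.0)
        if n == 0:
            raise AlignmentError("series have no overlapping valid samples")
        return SeriesComparison(rmse=value, n_points=n, alignment="linear")

    dt = np.median(np.diff(ta)) if len(ta) > 1 else max_lag_s
    lags = np.arange(-max_lag_s, max_lag_s + dt / 2, dt)
    best = (np.inf, 0, 0.0)
    for lag in lags:
        value, n = _rmse_at_lag(float(lag))
        if n > 0 and value < best[0]:
            best = (value, n, float(lag))
    if best[1] == 0:
        raise AlignmentError("series have no overlapping valid samples at any lag")
    return SeriesComparison(
        rmse=best[0], n_points=best[1], alignment=f"xcorr lag={best[2]:.3f}s"
    )


def error_report(
    measured: float, reference: float, denom: str = "ground_truth"
) -> ErrorReport:
    return ErrorReport(
        measured=float(measured),
        reference=float(reference),
        absolute_error=absolute_error(measured, reference),
        relative_error_pct=relative_error(measured, reference, denom),
        denominator=denom,
    )


def comparison_table(
    rows: Sequence[tuple[str, float, float, str]],
    decimals: int = 2,
    rounding: str = "round",
) -> pd.DataFrame:
    """Measured/reference error table in the standard validation layout.

    Each row is (label, measured, reference, denominator convention).  The
    returned frame carries both full-precision and display-rounded error
    columns; ``decimals`` is typically 2 for length tables and 1 for joint
    amplitude tables.
    """
    if not rows:
        raise ParameterError("comparison_table requires at least one row")
    records = []
    for label, measured, reference, denom in rows:
        rep = error_report(measured, reference, denom)
        records.append(
            {
                "label": label,
                "measured": rep.measured,
                "reference": rep.reference,
                "absolute_error": rep.absolute_error,
                "relative_error_pct": rep.relative_error_pct,
                "absolute_error_display": round_report(
                    rep.absolute_error, decimals, rounding
                ),
                "relative_error_pct_display": round_report(
                    rep.relative_error_pct, decimals, rounding
                ),
                "denominator": denom,
            }
        )
    return pd.DataFrame.from_records(records)
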