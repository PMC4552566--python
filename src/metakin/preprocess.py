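"""Alignment of variable-length trajectories onto a common relative axis.

Subjects differ in their maximum workload, so their sampled trajectories
differ in length.  They are made comparable by rescaling each subject's
sampling axis — rest to 0%, the individual maximum workload to 100%, the
recovery sample to a common position (117% by default, the cohort median
of 100*t_recovery/t_max in the reference study) — followed by piecewise
linear interpolation onto a shared grid and pointwise median extraction.
The median is what downstream modelling consumes; it is what makes the
pipeline indifferent to isolated outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, RECOVERY, REST
from .simulate import RECOVERY_POSITION

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RescaledSeries:
    """One subject's series on the relative-workload axis, missing dropped."""

    subject_id: str
    metabolite: str
    positions: np.ndarray  # strictly increasing, first 0, last = recovery position
    values: np.ndarray  # uM, same length


@dataclass(frozen=True)
class Grid:
    """Evenly spaced relative-workload positions from 0 to recovery.

    Always contains 0, 100 and the recovery position exactly; with the
    defaults (step 1, recovery 117) that is 118 points.
    """

    step: float = 1.0
    recovery_position: float = RECOVERY_POSITION

    @property
    def positions(self) -> np.ndarray:
        pos = np.arange(0.0, self.recovery_position + self.step / 2, self.step)
        pos = pos[pos <= self.recovery_position + 1e-9]
        for anchor in (100.0, self.recovery_position):
            if not np.isclose(pos, anchor).any():
                pos = np.sort(np.append(pos, anchor))
        return pos

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class InterpolatedCurve:
    """A subject's curve on the grid, defined only on its observed support."""

    subject_id: str
    metabolite: str
    grid: Grid
    values: np.ndarray  # NaN outside observed_support

    @property
    def observed_support(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class MedianCurve:
    metabolite: str
    grid: Grid
    values: np.ndarray


def rescale_series(
    series: pd.DataFrame,
    recovery_position: float = RECOVERY_POSITION,
) -> RescaledSeries | None:
    """Map one subject-metabolite series onto the relative-workload axis.

    Rest maps to 0, level k to 100*W_k/W_max (W_max is the subject's
    highest *protocol* workload, present or not in the data), recovery to
    ``recovery_position``.  Missing concentrations are dropped together
    with their positions.  Series with fewer than 3 usable samples are
    skipped (returns None) with a logged warning.
    """
    stages = series["stage"].to_numpy()
    if REST not in stages or RECOVERY not in stages:
        raise ValueError("series must contain rest and recovery stages")
    w = series["workload_w"].to_numpy(float)
    w_max = np.nanmax(w) if np.isfinite(w).any() else np.nan
    positions = np.where(
        stages == REST, 0.0, np.where(stages == RECOVERY, recovery_position, 100.0 * w / w_max)
    )
    values = series["concentration_um"].to_numpy(float)
    keep = ~np.isnan(values)
    if keep.sum() < 3:
        logger.warning(
            "series %s/%s has %d usable samples; skipped",
            series["subject_id"].iloc[0],
            series["metabolite"].iloc[0],
            int(keep.sum()),
        )
        return None
    return RescaledSeries(
        subject_id=str(series["subject_id"].iloc[0]),
        metabolite=str(series["metabolite"].iloc[0]),
        positions=positions[keep],
        values=values[keep],
    )


def median_recovery_position(cohort: Cohort, default: float = RECOVERY_POSITION) -> float:
    """Cohort median of 100 * t_recovery / t_max from sample timestamps.

    t_max is the timestamp of the subject's maximum-workload sample and
    t_recovery the recovery timestamp.  Subjects lacking either timestamp
    are ignored; with no usable subject the configured default (117) is
    returned with a logged notice.
    """
    ratios: list[float] = []
    met0 = cohort.metabolites[0]
    for _, series in cohort.iter_series(met0):
        levels = series[~series["stage"].isin([REST, RECOVERY])]
        rec = series[series["stage"] == RECOVERY]
        if levels.empty or rec.empty:
            continue
        t_max = levels.loc[levels["workload_w"].idxmax(), "time_min"]
        t_rec = rec["time_min"].iloc[0]
        if np.isnan(t_max) or np.isnan(t_rec) or t_max <= 0:
            continue
        ratios.append(100.0 * float(t_rec) / float(t_max))
    if not ratios:
        logger.info("no usable timestamps; falling back to recovery position %g", default)
        return default
    return float(np.median(ratios))


def interpolate_curve(series: RescaledSeries, grid: Grid) -> InterpolatedCurve:
    """Piecewise-linear interpolation of a rescaled series onto the grid.

    Grid points coinciding with sample positions reproduce the sample
    values exactly; interior gaps (e.g. a missing maximum-load sample)
    are bridged by a single linear segment; there is no extrapolation
    outside the observed support.
    """
    pos = grid.positions
    values = np.interp(pos, series.positions, series.values)
    outside = (pos < series.positions[0] - 1e-12) | (pos > series.positions[-1] + 1e-12)
    values[outside] = np.nan
    return InterpolatedCurve(series.subject_id, series.metabolite, grid, values)


def interpolate_cohort(
    cohort: Cohort,
    grid: Grid | None = None,
    recovery_position: float | None = None,
) -> dict[str, list[InterpolatedCurve]]:
    """Rescale and interpolate every subject-metabolite series.

    Returns per-metabolite lists of interpolated curves; series with too
    few usable samples are dropped (logged by :func:`rescale_series`).
    """
    if recovery_position is None:
        recovery_position = grid.recovery_position if grid is not None else RECOVERY_POSITION
    if grid is None:
        grid = Grid(recovery_position=recovery_position)
    out: dict[str, list[InterpolatedCurve]] = {}
    for metabolite in cohort.metabolites:
        curves: list[InterpolatedCurve] = []
        for _, series in cohort.iter_series(metabolite):
            rescaled = rescale_series(series, recovery_position=recovery_position)
            if rescaled is not None:
                curves.append(interpolate_curve(rescaled, grid))
        out[metabolite] = curves
    return out


def extract_median_curves(
    curves: dict[str, list[InterpolatedCurve]],
) -> dict[str, MedianCurve]:
    """Pointwise median over subjects, ignoring undefined grid points.

    Even-count medians are the mean of the two central order statistics.
    A grid point at which no subject contributes is a hard error naming
    the metabolite and position.
    """
    medians: dict[str, MedianCurve] = {}
    for metabolite, curve_list in curves.items():
        if not curve_list:
            raise ValueError(f"no usable curves for metabolite {metabolite!r}")
        grid = curve_list[0].grid
        stack = np.vstack([c.values for c in curve_list])
        counts = (~np.isnan(stack)).sum(axis=0)
        if (counts == 0).any():
            bad = grid.positions[counts == 0][0]
            raise ValueError(
                f"metabolite {metabolite!r}: no subject defined at grid position {bad:g}"
            )
        medians[metabolite] = MedianCurve(metabolite, grid, np.nanmedian(stack, axis=0))
    return medians


def curves_to_frame(
    curves: dict[str, list[InterpolatedCurve]],
    medians: dict[str, MedianCurve] | None = None,
) -> pd.DataFrame:
    """Long-format export: metabolite, position, subject_id, value_um.

    Median rows use subject_id ``"MEDIAN"``.  Undefined points are
    omitted.
    """
    rows: list[pd.DataFrame] = []
    for metabolite, curve_list in curves.items():
        for c in curve_list:
            mask = c.observed_support
            rows.append(
                pd.DataFrame(
                    {
                        "metabolite": metabolite,
                        "position": c.grid.positions[mask],
                        "subject_id": c.subject_id,
                        "value_um": c.values[mask],
                    }
                )
            )
    if medians:
        for metabolite, m in medians.items():
            rows.append(
                pd.DataFrame(
                    {
                        "metabolite": metabolite,
                        "position": m.grid.positions,
                        "subject_id": "MEDIAN",
                        "value_um": m.values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
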