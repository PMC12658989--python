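"""Root-growth inhibition and EC50 estimation for the Allium cepa bioassay.

The assay exposes germinating *A. cepa* roots to a dilution series of a test
substance and measures root length after a fixed time.  Toxic potency is
summarised as the EC50: the concentration that reduces mean root growth by
50 % relative to the concurrent water control.  Following common practice for
this bioassay, inhibition is assumed linear in concentration over the tested
range, so the EC50 is obtained by ordinary least squares of percent inhibition
on concentration and inverting the fitted line at 50 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TREATMENT_LABELS = ("negative_control", "single", "combined", "positive_control")


@dataclass(frozen=True)
class RootGrowthRecord:
    """One root-length measurement under a treatment/concentration/exposure."""

    treatment: str
    concentration: float  # mg/mL
    exposure_h: float
    replicate: int
    length_mm: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENT_LABELS:
            raise ValueError(f"unknown treatment label {self.treatment!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.treatment == "negative_control" and self.concentration != 0:
            raise ValueError("negative control must have concentration 0")
        if self.length_mm < 0:
            raise ValueError("root length must be >= 0")


def records_to_frame(records: Iterable[RootGrowthRecord]) -> pd.DataFrame:
    rows = [
        (r.treatment, r.concentration, r.exposure_h, r.replicate, r.length_mm)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["treatment", "concentration", "exposure_h", "replicate", "length_mm"],
    )


def inhibition_percent(treated_mean: float, control_mean: float) -> float:
    """Percent inhibition of root growth relative to the control mean.

    Returns ``100 * (1 - treated_mean / control_mean)``.  Negative values mean
    the treatment stimulated growth beyond the control.
    """
    if control_mean <= 0:
        raise ValueError("control mean length must be > 0")
    return 100.0 * (1.0 - treated_mean / control_mean)


@dataclass
class DoseResponseFit:
    """Fitted inhibition-vs-concentration line with the EC50 it implies."""

    slope: float  # % per (mg/mL)
    intercept: float  # %
    r_squared: float
    ec50: float | None  # mg/mL; None when slope <= 0 (no inhibition signal)
    concentrations_used: tuple[float, ...]
    n_points: int

    def ec(self, level: float) -> float:
        """Concentration producing ``level`` percent inhibition (regression-based EC_x)."""
        if self.slope is None or self.slope <= 0:
            raise ValueError("EC_x undefined: fitted slope is not positive")
        return (level - self.intercept) / self.slope


@dataclass(frozen=True)
class DerivedConcentrations:
    """The three test concentrations used downstream: 0.5x, 1x and 1.5x EC50."""

    low: float
    mid: float
    high: float


def fit_ec50(points: Sequence[tuple[float, float]]) -> DoseResponseFit:
    """OLS of percent inhibition on concentration; EC50 = (50 - b) / m.

    ``points`` are (concentration mg/mL, inhibition %) pairs; the fit is
    invariant to their ordering.  A non-positive slope leaves the EC50 as
    ``None`` (the substance does not inhibit growth over the tested range).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, inhibition%) pairs")
    conc, inh = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("need at least two distinct concentrations")
    res = stats.linregress(conc, inh)
    slope, intercept = float(res.slope), float(res.intercept)
    ec50 = (50.0 - intercept) / slope if slope > 0 else None
    return DoseResponseFit(
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rvalue) ** 2,
        ec50=ec50,
        concentrations_used=tuple(sorted(set(conc.tolist()))),
        n_points=len(pts),
    )


def inhibition_points(
    frame: pd.DataFrame,
    exposure_h: float | None = None,
    per_replicate: bool = True,
) -> list[tuple[float, float]]:
    """Turn a long root-length table into (concentration, inhibition %) points.

    The control mean is taken from the concentration-0 group at the same
    exposure.  With ``per_replicate=True`` (default) every root contributes a
    point; otherwise one point per concentration from the group mean.
    """
    df = frame
    if exposure_h is not None:
        df = df[df["exposure_h"] == exposure_h]
    if df.empty:
        raise ValueError("no records for requested exposure")
    control = df[df["concentration"] == 0]["length_mm"]
    if control.empty:
        raise ValueError("no concentration-0 control group present")
    control_mean = float(control.mean())
    treated = df[df["concentration"] > 0]
    pts: list[tuple[float, float]] = []
    if per_replicate:
        for c, length in zip(treated["concentration"], treated["length_mm"]):
            pts.append((float(c), inhibition_percent(float(length), control_mean)))
    else:
        for c, grp in treated.groupby("concentration"):
            pts.append((float(c), inhibition_percent(float(grp["length_mm"].mean()), control_mean)))
    return pts


def fit_ec50_from_records(
    records: Iterable[RootGrowthRecord] | pd.DataFrame,
    exposure_h: float | None = None,
    per_replicate: bool = True,
) -> DoseResponseFit:
    """Convenience wrapper: records/table -> inhibition points -> EC50 fit."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    return fit_ec50(inhibition_points(frame, exposure_h=exposure_h, per_replicate=per_replicate))


def derive_test_concentrations(ec50: float) -> DerivedConcentrations:
    """The study design's three concentrations: (0.5, 1, 1.5) x EC50."""
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    return DerivedConcentrations(low=0.5 * ec50, mid=ec50, high=1.5 * ec50)


def summarize_root_growth(
    records: Iterable[RootGrowthRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Mean +/- sample SD and n per (treatment, concentration, exposure) group.

    SD uses the n-1 convention; a singleton group reports SD as missing (NaN)
    rather than zero.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to summarize")
    out = (
        frame.groupby(["treatment", "concentration", "exposure_h"])["length_mm"]
        .agg(mean_mm="mean", sd_mm=lambda s: s.std(ddof=1), n="size")
        .reset_index()
    )
    out.loc[out["n"] == 1, "sd_mm"] = np.nan
    return out
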