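"""Bioactivity screening analytics.

Three assay families are covered:

* MTT cytotoxicity — percent growth inhibition from plate absorbances,
  screening summaries at an inhibition threshold, and IC50 estimation
  by a four-parameter logistic (4PL) fit with censoring at the tested
  concentration range;
* agar disc diffusion — zone-of-inhibition activity summaries;
* broth dilution — MIC endpoint logic with ">max" right-censoring and
  screening summaries.

IC50 censoring follows screening-report convention: if inhibition is
already >= 50% at the lowest tested concentration the estimate is
reported as "< min" rather than extrapolated, and symmetrically
"> max" when 50% is never reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseSeries",
    "IC50Estimate",
    "percent_growth_inhibition",
    "cytotoxic_screen_summary",
    "fit_ic50",
    "ic50_activity_counts",
    "zi_screen_summary",
    "mic_from_dilution",
    "mic_screen_summary",
]


@dataclass(frozen=True)
class DoseResponseSeries:
    """Concentration-inhibition points for one extract on one cell line."""

    extract_id: str
    cell_line: str
    points: tuple[tuple[float, float], ...]  # (concentration ug/mL, %GI)

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise ValueError("duplicate concentrations")
        if any(not math.isfinite(g) for _, g in self.points):
            raise ValueError("non-finite inhibition value")

    def sorted_points(self) -> tuple[np.ndarray, np.ndarray]:
        pts = sorted(self.points)
        return np.array([c for c, _ in pts]), np.array([g for _, g in pts])


@dataclass(frozen=True)
class IC50Estimate:
    """A possibly censored half-inhibition concentration (ug/mL)."""

    value: float
    censor: str = "exact"  # exact | below_min | above_max
    fit_params: tuple[float, float, float, float] | None = None  # lower, upper, hill, ic50

    def __str__(self) -> str:
        if self.censor == "below_min":
            return f"<{self.value:g}"
        if self.censor == "above_max":
            return f">{self.value:g}"
        return f"{self.value:g}"


def percent_growth_inhibition(od_treated, od_control, od_blank) -> float:
    """%GI = (1 - (OD_t - OD_b) / (OD_c - OD_b)) * 100.

    Blank-subtracted viability relative to the untreated control; may
    fall below 0 or above 100 with assay noise.  Requires a viable
    control signal (OD_c > OD_b).
    """
    od_treated = np.asarray(od_treated, dtype=float)
    od_control = np.asarray(od_control, dtype=float)
    od_blank = np.asarray(od_blank, dtype=float)
    if np.any(od_control <= od_blank):
        raise ValueError("control absorbance must exceed blank")
    gi = (1.0 - (od_treated - od_blank) / (od_control - od_blank)) * 100.0
    return float(gi) if gi.ndim == 0 else gi


def cytotoxic_screen_summary(inhibition: pd.DataFrame, threshold: float = 50.0) -> dict:
    """Summarize an extract x cell-line %GI matrix at a strict threshold.

    An extract is counted per line when its inhibition is strictly
    above ``threshold``; "any-line" requires at least one such line and
    "all-line" every line.  NaN entries never pass.
    """
    if inhibition.empty:
        raise ValueError("empty inhibition matrix")
    active = inhibition.gt(threshold)
    n = len(inhibition)
    any_n = int(active.any(axis=1).sum())
    all_n = int(active.all(axis=1).sum())
    return {
        "n_extracts": n,
        "any_line_active": any_n,
        "any_line_fraction": any_n / n,
        "all_line_active": all_n,
        "all_line_fraction": all_n / n,
        "per_line_active": active.sum(axis=0).astype(int).to_dict(),
    }


def _four_pl(logc: np.ndarray, lower: float, upper: float, hill: float, log_ic50: float):
    return lower + (upper - lower) / (1.0 + np.exp(hill * (log_ic50 - logc)))


def _interp_ic50(conc: np.ndarray, gi: np.ndarray) -> float:
    """Log-linear interpolation between the points bracketing 50%."""
    for k in range(len(conc) - 1):
        g0, g1 = gi[k], gi[k + 1]
        if (g0 - 50.0) * (g1 - 50.0) <= 0:
            if g1 == g0:
                return float(conc[k])
            x0, x1 = math.log(conc[k]), math.log(conc[k + 1])
            return float(math.exp(x0 + (50.0 - g0) * (x1 - x0) / (g1 - g0)))
    raise RuntimeError("no bracketing points for 50%")  # pragma: no cover


def fit_ic50(series: DoseResponseSeries) -> IC50Estimate:
    """Estimate IC50 from a dose-response series.

    Censoring is decided first: >= 50% inhibition at the lowest tested
    concentration reports ``below_min`` ("< min"), < 50% at the highest
    reports ``above_max``.  Otherwise a 4PL curve

        %GI(c) = lower + (upper - lower) / (1 + (IC50/c)^hill)

    is fitted by least squares on log-concentration; if the fit fails
    or yields a non-increasing curve, the estimate falls back to
    log-linear interpolation between the two points bracketing 50%.
    """
    conc, gi = series.sorted_points()
    if len(conc) < 2:
        raise ValueError("need at least 2 dose-response points")
    if gi[0] >= 50.0:
        return IC50Estimate(value=float(conc[0]), censor="below_min")
    if gi[-1] < 50.0:
        return IC50Estimate(value=float(conc[-1]), censor="above_max")

    logc = np.log(conc)
    guess = _interp_ic50(conc, gi)
    x0 = np.array([min(gi.min(), 0.0), max(gi.max(), 100.0), 1.0, math.log(guess)])
    lo = np.array([-100.0, 0.0, 0.05, math.log(conc[0]) - 5.0])
    hi = np.array([50.0, 300.0, 10.0, math.log(conc[-1]) + 5.0])

    try:
        sol = least_squares(
            lambda p: _four_pl(logc, *p) - gi,
            x0=np.clip(x0, lo, hi),
            bounds=(lo, hi),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        lower, upper, hill, log_ic50 = sol.x
        ok = sol.success and upper > lower and hill > 0
    except Exception:
        ok = False
    if not ok:
        return IC50Estimate(value=guess, censor="exact", fit_params=None)

    ic50 = float(math.exp(log_ic50))
    # the fitted curve must actually reach 50% inside the tested range;
    # a flat fit (upper barely above lower) signals a failed model
    if not (lower < 50.0 < upper) or not (conc[0] <= ic50 <= conc[-1]):
        return IC50Estimate(value=guess, censor="exact", fit_params=None)
    # place the estimate where the fitted curve crosses 50%
    frac = (50.0 - lower) / (upper - lower)
    cross = float(math.exp(log_ic50 - math.log(1.0 / frac - 1.0) / hill)) if 0 < frac < 1 else ic50
    return IC50Estimate(
        value=cross,
        censor="exact",
        fit_params=(float(lower), float(upper), float(hill), ic50),
    )


def ic50_activity_counts(table: pd.DataFrame, threshold: float = 20.0) -> dict:
    """Count extracts with IC50 below a potency threshold.

    ``table`` is long form with columns extract_id, cell_line, ic50,
    censor.  A ``below_min`` entry counts as active when its bound is
    below the threshold; ``above_max`` entries never do.
    """
    if table.empty:
        raise ValueError("empty IC50 table")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    active = (table["ic50"] < threshold) & (table["censor"] != "above_max")
    t = table.assign(active=active)
    per_line = t.groupby("cell_line")["active"].apply(lambda s: int(s.sum())).to_dict()
    any_line = int(t.groupby("extract_id")["active"].any().sum())
    return {"any_line_active": any_line, "per_line_active": per_line}


def zi_screen_summary(panel: pd.DataFrame) -> dict:
    """Disc-diffusion activity summary.

    ``panel`` is long form with columns extract_id, pathogen, zi_mm
    (NaN = no zone recorded).  An extract is active against a pathogen
    iff a zone is recorded; "overall" means active against >= 1.
    """
    t = panel.assign(active=panel["zi_mm"].notna())
    n = t["extract_id"].nunique()
    by_extract = t.groupby("extract_id")["active"].any()
    per_pathogen = t.groupby("pathogen")["active"].sum().astype(int).to_dict()
    overall = int(by_extract.sum())
    return {
        "n_extracts": n,
        "overall_active": overall,
        "overall_fraction": overall / n if n else 0.0,
        "per_pathogen_active": per_pathogen,
        "per_pathogen_fraction": {k: v / n for k, v in per_pathogen.items()} if n else {},
    }


def mic_from_dilution(growth, concentrations) -> tuple[float, str]:
    """MIC endpoint from a dilution series of growth flags.

    ``growth[i]`` is True when visible growth occurred at
    ``concentrations[i]`` (sorted ascending).  The MIC is the lowest
    concentration above which no growth occurs at any tested level.
    Returns ``(value, censor)`` with censor ``exact``, ``gt`` (growth
    everywhere, MIC > max) or ``le`` (clear everywhere, MIC <= min).
    A well pattern where growth reappears above a clear concentration
    is biologically invalid and raises ``ValueError``.
    """
    growth = [bool(g) for g in growth]
    concentrations = [float(c) for c in concentrations]
    if not concentrations:
        raise ValueError("empty concentration series")
    if len(growth) != len(concentrations):
        raise ValueError("growth flags and concentrations differ in length")
    if sorted(concentrations) != concentrations:
        raise ValueError("concentrations must be sorted ascending")

    if all(growth):
        return concentrations[-1], "gt"
    first_clear = growth.index(False)
    if any(growth[first_clear:]):
        raise ValueError(
            "invalid well: growth reappears above a clear concentration "
            f"(flags {growth})"
        )
    if first_clear == 0:
        return concentrations[0], "le"
    return concentrations[first_clear], "exact"


def mic_screen_summary(panel: pd.DataFrame, cutoff: float = 100.0) -> dict:
    """Broth-dilution activity summary.

    An extract is active when it has at least one non-right-censored
    MIC <= ``cutoff`` against any pathogen.  ``panel`` is long form
    with columns extract_id, pathogen, mic, censor (``exact``, ``le``,
    ``gt`` or ``none`` for untested/inactive cells).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ok = panel["censor"].isin(["exact", "le", "lt"]) & (panel["mic"] <= cutoff)
    t = panel.assign(active=ok)
    per_pathogen = t.groupby("pathogen")["active"].sum().astype(int).to_dict()
    overall = int(t.groupby("extract_id")["active"].any().sum())
    return {
        "n_extracts": t["extract_id"].nunique(),
        "overall_active": overall,
        "per_pathogen_active": per_pathogen,
    }
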