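"""Treatment-response assay mathematics.

Clonogenic survival: the plating efficiency (PE) is colonies counted per
cells plated x 100%; the survival fraction (SF) is the PE of treated
cells over the PE of untreated controls x 100%.

Apoptosis flow cytometry: viable percentages are normalized to the
vehicle control; vehicle early/late apoptotic background is subtracted
from treated values (clamped at zero, with the clamp flagged).

Dose response: a four-parameter logistic (4PL)

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

is fitted by least squares (log-IC50 internally, multi-start); the IC50
is the curve midpoint (relative IC50).  With viability decreasing in
dose, hill > 0 under this sign convention.

Densitometry: band intensities are divided by a per-lane loading factor,
lane intensity over the brightest lane on the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit


# ---------------------------------------------------------------------------
# clonogenic survival
# ---------------------------------------------------------------------------

def plating_efficiency(colonies, cells_plated) -> float:
    """PE (%) = colonies / cells plated x 100."""
    colonies = np.asarray(colonies, dtype=float)
    cells_plated = np.asarray(cells_plated, dtype=float)
    if np.any(cells_plated <= 0):
        raise ValueError("cells_plated must be > 0")
    if np.any(colonies < 0):
        raise ValueError("colonies must be >= 0")
    if np.any(colonies > cells_plated):
        raise ValueError("more colonies than cells plated")
    out = colonies / cells_plated * 100.0
    return float(out) if out.ndim == 0 else out


def survival_fraction(pe_treated, pe_control) -> float:
    """SF (%) = PE(treated) / PE(control) x 100."""
    pe_treated = np.asarray(pe_treated, dtype=float)
    pe_control = np.asarray(pe_control, dtype=float)
    if np.any(pe_control <= 0):
        raise ValueError("control plating efficiency must be > 0")
    out = pe_treated / pe_control * 100.0
    return float(out) if out.ndim == 0 else out


def clonogenic_survival(
    counts: pd.DataFrame,
    control_dose: float = 0.0,
    mode: str = "per_replicate",
) -> pd.DataFrame:
    """Summarize a clonogenic count table into SF per sample and dose.

    ``counts`` columns: sample, dose_gy, cells_plated, colonies,
    replicate.  ``mode="per_replicate"`` computes SF for every treated
    replicate against the mean control PE and averages (the reported
    mean +/- SD is over replicates); ``mode="pooled"`` sums colonies and
    cells first.
    """
    required = {"sample", "dose_gy", "cells_plated", "colonies"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    rows = []
    for sample, grp in counts.groupby("sample", sort=False):
        ctrl = grp[grp["dose_gy"] == control_dose]
        if ctrl.empty:
            raise ValueError(f"sample {sample!r} has no dose {control_dose} control")
        if mode == "per_replicate":
            pe_ctrl = plating_efficiency(ctrl["colonies"], ctrl["cells_plated"]).mean()
        elif mode == "pooled":
            pe_ctrl = plating_efficiency(ctrl["colonies"].sum(),
                                         ctrl["cells_plated"].sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for dose, dgrp in grp[grp["dose_gy"] != control_dose].groupby("dose_gy"):
            if mode == "per_replicate":
                sf = survival_fraction(
                    plating_efficiency(dgrp["colonies"], dgrp["cells_plated"]),
                    pe_ctrl,
                )
                sf = np.atleast_1d(sf)
                mean_sf, sd_sf = float(np.mean(sf)), float(np.std(sf, ddof=1)) if len(sf) > 1 else 0.0
            else:
                mean_sf = survival_fraction(
                    plating_efficiency(dgrp["colonies"].sum(),
                                       dgrp["cells_plated"].sum()),
                    pe_ctrl,
                )
                sd_sf = float("nan")
            rows.append((sample, dose, mean_sf, sd_sf, len(dgrp)))
    return pd.DataFrame(rows, columns=["sample", "dose_gy", "sf_pct",
                                       "sf_sd", "n_replicates"])


# ---------------------------------------------------------------------------
# apoptosis normalization
# ---------------------------------------------------------------------------

@dataclass
class ApoptosisRecord:
    """One flow-cytometry quadrant readout (% of events)."""

    viable_pct: float
    early_apoptotic_pct: float
    late_apoptotic_pct: float
    dose: float = 0.0
    vehicle: bool = False

    def __post_init__(self) -> None:
        for name in ("viable_pct", "early_apoptotic_pct", "late_apoptotic_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        total = self.viable_pct + self.early_apoptotic_pct + self.late_apoptotic_pct
        if total > 100 + 1e-9:
            raise ValueError("quadrant percentages sum beyond 100%")


def normalize_apoptosis(treated: ApoptosisRecord, vehicle: ApoptosisRecord) -> dict:
    """Vehicle-normalize a treated quadrant readout.

    Viability is expressed relative to vehicle (x 100); vehicle apoptotic
    background is subtracted from the treated apoptotic fractions,
    clamping at zero with an audit flag.
    """
    if vehicle.viable_pct <= 0:
        raise ValueError("vehicle viable percentage must be > 0")
    early = treated.early_apoptotic_pct - vehicle.early_apoptotic_pct
    late = treated.late_apoptotic_pct - vehicle.late_apoptotic_pct
    return {
        "viable_norm_pct": treated.viable_pct / vehicle.viable_pct * 100.0,
        "early_apoptotic_pct": max(early, 0.0),
        "late_apoptotic_pct": max(late, 0.0),
        "early_clamped": early < 0,
        "late_clamped": late < 0,
        "dose": treated.dose,
    }


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    """Fitted four-parameter logistic dose-response curve."""

    bottom: float
    top: float
    ic50: float           # curve midpoint dose (relative IC50)
    hill: float
    rss: float
    converged: bool
    ic50_absolute: float | None = None  # dose where y crosses 50 response units

    def __call__(self, dose) -> float:
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)


def four_pl(x, bottom: float, top: float, ic50: float, hill: float):
    """Evaluate y = bottom + (top - bottom)/(1 + (x/ic50)^hill) for x > 0."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.power(x / ic50, hill))


def _4pl_log(x, bottom, top, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(x) - log_ic50)))


def fit_4pl(doses, responses, n_hill_starts: int = 4,
            bounded: bool = True) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    Requires >= 5 distinct positive doses.  IC50 is fitted on the log
    scale for stability; starts sweep the dose range and both Hill-slope
    orientations.  By default the asymptotes are constrained to the
    observed response range (plus a 25% margin), the IC50 to within one
    decade of the tested dose range and |hill| <= 10 — with a handful of
    noisy points an unconstrained 4PL can run its asymptotes far outside
    anything a viability readout can produce.  Raises on non-convergence
    of every start.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(x <= 0):
        raise ValueError("doses must be > 0 (drop the vehicle point)")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if len(np.unique(x)) < 5:
        raise ValueError("need >=5 distinct doses spanning the inflection")

    ymin, ymax = float(y.min()), float(y.max())
    span = max(ymax - ymin, 1e-12)
    if bounded:
        margin = 0.25 * span
        lb = [ymin - margin, ymin - margin, np.log(x.min()) - np.log(10.0), -10.0]
        ub = [ymax + margin, ymax + margin, np.log(x.max()) + np.log(10.0), 10.0]
        bounds = (lb, ub)
    else:
        bounds = (-np.inf, np.inf)
    log_starts = np.quantile(np.log(np.unique(x)), [0.25, 0.5, 0.75])
    hill_starts = [0.5, 1.0, 2.0, 4.0][:n_hill_starts]
    best = None
    for ls in log_starts:
        for h0 in hill_starts:
            for sign in (1.0, -1.0):
                p0 = (ymin, ymax, ls, sign * h0)
                try:
                    with warnings.catch_warnings():
                        # perfect fits make the covariance singular; only
                        # the point estimate matters here
                        warnings.simplefilter("ignore", OptimizeWarning)
                        popt, _ = curve_fit(_4pl_log, x, y, p0=p0,
                                            bounds=bounds, maxfev=20000)
                except (RuntimeError, ValueError):
                    continue
                resid = y - _4pl_log(x, *popt)
                rss = float(resid @ resid)
                if best is None or rss < best[1]:
                    best = (popt, rss)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from any start")
    (bottom, top, log_ic50, hill), rss = best
    # canonical orientation: top >= bottom, hill sign flipped to match
    if bottom > top:
        bottom, top, hill = top, bottom, -hill
    fit = FourPLFit(
        bottom=float(bottom),
        top=float(top),
        ic50=float(np.exp(log_ic50)),
        hill=float(hill),
        rss=rss,
        converged=bool(np.isfinite(rss)),
    )
    fit.ic50_absolute = _absolute_ic50(fit)
    return fit


def _absolute_ic50(fit: FourPLFit, level: float = 50.0) -> float | None:
    """Dose at which the fitted curve crosses an absolute response level."""
    lo, hi = min(fit.bottom, fit.top), max(fit.bottom, fit.top)
    if not lo < level < hi:
        return None
    frac = (fit.top - level) / (level - fit.bottom)
    if frac <= 0:
        return None
    return float(fit.ic50 * frac ** (1.0 / fit.hill))


def interpolate_at(fit: FourPLFit, dose) -> float:
    """Evaluate a converged 4PL fit at a dose (> 0)."""
    if not fit.converged:
        raise ValueError("cannot interpolate from a non-converged fit")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be > 0")
    out = four_pl(dose, fit.bottom, fit.top, fit.ic50, fit.hill)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------

def densitometry_normalize(lane_intensities, band_intensities):
    """Total-protein loading normalization of band intensities.

    factor_i = lane_i / max(lane); normalized band_i = band_i / factor_i.
    Scaling every lane by a constant leaves the output unchanged.
    """
    lanes = np.asarray(lane_intensities, dtype=float)
    bands = np.asarray(band_intensities, dtype=float)
    if lanes.shape != bands.shape:
        raise ValueError("lane and band vectors must have equal length")
    if np.any(lanes <= 0) or np.any(bands <= 0):
        raise ValueError("intensities must be > 0")
    factors = lanes / lanes.max()
    return bands / factors
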