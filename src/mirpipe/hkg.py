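"""Reference-miRNA (housekeeping gene, HKG) selection for qPCR panels.

Implements a Bianchi-style multi-criterion screen on a detection-filtered
Ct matrix.  An assay qualifies as a reference if

(i)   it is detected in every sample and highly expressed
      (median Ct below a cap, default 30 cycles);
(ii)  it does not differ between the two contrast conditions
      (two-sided Mann-Whitney U, p above a floor, default 0.1);
(iii) it is not unusually variable on the linear 2^-Ct scale — its
      coefficient of variation stays below mean(CV) + k*SD(CV) computed
      over the criterion-(i) survivors — and no sample deviates more
      than a fold-window (default 5x) from the assay's mean level;
(iv)  its profile correlates (Pearson r above a floor, default 0.7) with
      the running reference — the per-sample geometric mean of the
      surviving candidates on the linear scale, equivalently the
      arithmetic mean of their Ct values.  Criterion (iv) is iterated:
      the reference is recomputed from survivors until a fixed point.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_io import OK, CtMatrix, GroupDesign

_EPS_SD = 1e-12


class SelectionError(ValueError):
    """Raised when the criterion cascade empties the candidate set."""


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

#: at or below this combined size, auto mode enumerates all assignments
EXACT_ENUMERATION_LIMIT = 12


def mann_whitney_u(x, y, mode: str = "auto"):
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates every assignment of the pooled data into
    groups of the observed sizes (midranks, so ties are handled by the
    permutation distribution of the tied data); ``"approx"`` uses the
    tie-corrected normal approximation with continuity correction;
    ``"auto"`` picks exact when n1+n2 <= 12.

    Returns ``(U, p)`` where U is the statistic of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_ENUMERATION_LIMIT else "approx"

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if mode == "exact":
        n = n1 + n2
        total = 0
        extreme = 0
        dev_obs = abs(u_obs - mu)
        for idx in itertools.combinations(range(n), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                extreme += 1
        p = extreme / total
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:  # all values tied
            return u_obs, 1.0
        z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * stats.norm.sf(z))
    return u_obs, min(max(p, np.finfo(float).tiny), 1.0)


# ---------------------------------------------------------------------------
# reference profile
# ---------------------------------------------------------------------------

def geometric_mean_reference(m: CtMatrix | pd.DataFrame, hkgs) -> pd.Series:
    """Per-sample reference Ct: arithmetic mean over the HKG set.

    On the linear 2^-Ct scale this is the geometric mean of the HKG
    relative quantities (2^-mean(Ct) = geomean(2^-Ct)).
    """
    hkgs = list(hkgs)
    if not hkgs:
        raise ValueError("HKG set is empty")
    if isinstance(m, CtMatrix):
        missing = [h for h in hkgs if h not in m.ct.index]
        if missing:
            raise ValueError(f"HKGs not in matrix: {missing}")
        sub = m.ct.loc[hkgs]
        if not (m.status.loc[hkgs].to_numpy() == OK).all():
            bad = m.status.loc[hkgs].index[
                (m.status.loc[hkgs] != OK).any(axis=1)
            ][0]
            raise ValueError(f"HKG {bad!r} is not detected in every sample")
    else:
        sub = m.loc[hkgs]
        if sub.isna().to_numpy().any():
            raise ValueError("HKG values contain undetected wells")
    return sub.mean(axis=0)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

@dataclass
class HkgCriteria:
    """Thresholds of the four-criterion screen.

    median_ct_max
        criterion (i) expression cap, cycles (default 30).
    stability_p_min
        criterion (ii) Mann-Whitney p floor; p must be strictly greater.
    cv_sd_multiplier
        criterion (iii) spread multiplier k in mean(CV) + k*SD(CV).
    outlier_fold
        criterion (iii) allowed fold window around the assay mean level.
    r_min
        criterion (iv) correlation floor; r must be strictly greater.
    """

    median_ct_max: float = 30.0
    stability_p_min: float = 0.1
    cv_sd_multiplier: float = 2.0
    outlier_fold: float = 5.0
    r_min: float = 0.7

    def __post_init__(self) -> None:
        for name in ("median_ct_max", "stability_p_min", "cv_sd_multiplier",
                     "outlier_fold", "r_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must lie in (0, 1)")
        if not 0 < self.stability_p_min < 1:
            raise ValueError("stability_p_min must lie in (0, 1)")


@dataclass
class HkgSelectionResult:
    selected: list
    diagnostics: pd.DataFrame
    iterations: int
    reference_profile: pd.Series
    criteria: HkgCriteria = field(default_factory=HkgCriteria)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "iterations": int(self.iterations),
            "reference_profile": {k: float(v) for k, v in self.reference_profile.items()},
            "criteria": vars(self.criteria).copy(),
            "diagnostics": self.diagnostics.reset_index()
            .rename(columns={"index": "assay"})
            .to_dict(orient="records"),
        }


def _pearson_vs_reference(values: np.ndarray, reference: np.ndarray) -> float:
    """Pearson r of an assay's -Ct profile against the -reference profile.

    Negating both series leaves r unchanged, so it is computed on Ct
    directly.  A candidate with (numerically) zero variance is a
    perfectly stable profile and scores r = 1; a varying candidate
    against a constant reference scores 0.
    """
    sx = values.std()
    sr = reference.std()
    if sx < _EPS_SD:
        return 1.0
    if sr < _EPS_SD:
        return 0.0
    return float(np.corrcoef(values, reference)[0, 1])


def select_hkgs(
    m: CtMatrix,
    design: GroupDesign,
    crit: HkgCriteria | None = None,
    mwu_mode: str = "auto",
    leave_self_out: bool = False,
) -> HkgSelectionResult:
    """Apply the four-criterion reference screen to a detection-filtered panel.

    With ``leave_self_out=True`` the criterion-(iv) reference excludes the
    candidate being scored; by default the candidate is part of the
    running geometric mean.
    """
    crit = crit or HkgCriteria()
    assays = m.assay_ids
    samples = m.sample_ids
    ct = m.ct
    detected_all = m.detected.all(axis=1)
    ref_samples = design.samples(design.reference)
    test_samples = design.samples(design.test)
    unknown = [s for s in samples if s not in design.condition_of]
    if unknown:
        raise ValueError(f"design does not cover samples: {unknown}")

    diag = pd.DataFrame(index=pd.Index(assays, name="assay"))
    diag["median_ct"] = ct.median(axis=1)
    diag["pass_i"] = detected_all & (diag["median_ct"] < crit.median_ct_max)

    # (ii) group stability
    pvals = {}
    for a in assays:
        if not diag.loc[a, "pass_i"]:
            pvals[a] = np.nan
            continue
        _, p = mann_whitney_u(
            ct.loc[a, ref_samples].to_numpy(),
            ct.loc[a, test_samples].to_numpy(),
            mode=mwu_mode,
        )
        pvals[a] = p
    diag["mwu_p"] = pd.Series(pvals)
    diag["pass_ii"] = diag["pass_i"] & (diag["mwu_p"] > crit.stability_p_min)

    # (iii) variability screen on the linear scale, calibrated on the
    # criterion-(i) survivors
    linear = np.power(2.0, -ct)
    cv = linear.std(axis=1, ddof=1) / linear.mean(axis=1)
    diag["cv"] = cv
    pool = cv[diag["pass_i"]]
    cv_cut = pool.mean() + crit.cv_sd_multiplier * pool.std(ddof=1)
    if not np.isfinite(cv_cut):  # single candidate: no spread to calibrate on
        cv_cut = np.inf
    mean_level = linear.mean(axis=1)
    lo = mean_level / crit.outlier_fold
    hi = mean_level * crit.outlier_fold
    outlier = (linear.lt(lo, axis=0) | linear.gt(hi, axis=0)).any(axis=1)
    diag["outlier_flag"] = outlier
    # tolerance keeps the degenerate zero-spread case (all candidate CVs
    # identical, SD(CV)=0) from rejecting every assay on a tie
    cv_pass = cv <= cv_cut + 1e-12 + 1e-9 * abs(cv_cut)
    diag["pass_iii"] = diag["pass_ii"] & cv_pass & ~outlier

    for crit_name, col in (("i", "pass_i"), ("ii", "pass_ii"), ("iii", "pass_iii")):
        if not diag[col].any():
            raise SelectionError(f"criterion ({crit_name}) removed every assay")

    # (iv) iterative geometric-mean correlation refinement
    current = [a for a in assays if diag.loc[a, "pass_iii"]]
    iterations = 0
    while True:
        iterations += 1
        reference = geometric_mean_reference(ct, current)
        r = {}
        for a in current:
            if leave_self_out and len(current) > 1:
                others = [b for b in current if b != a]
                ref_a = geometric_mean_reference(ct, others)
            else:
                ref_a = reference
            r[a] = _pearson_vs_reference(
                ct.loc[a].to_numpy(), ref_a.to_numpy()
            )
        survivors = [a for a in current if r[a] > crit.r_min]
        if not survivors:
            raise SelectionError("criterion (iv) removed every assay")
        if survivors == current:
            break
        current = survivors

    reference = geometric_mean_reference(ct, current)
    diag["r_with_geomean"] = pd.Series(
        {a: _pearson_vs_reference(ct.loc[a].to_numpy(), reference.to_numpy())
         for a in assays}
    )
    diag["pass_iv"] = diag["pass_iii"] & diag.index.isin(current)
    diag["selected"] = diag["pass_iv"]
    return HkgSelectionResult(
        selected=current,
        diagnostics=diag,
        iterations=iterations,
        reference_profile=reference,
        criteria=crit,
    )


# ---------------------------------------------------------------------------
# overlap of two reference sets
# ---------------------------------------------------------------------------

def hkg_overlap(a, b, denominator: str = "union", reference: str = "a") -> float:
    """Percent overlap between two selected reference sets.

    ``denominator`` chooses the normalization: ``"union"`` (Jaccard x 100,
    default), ``"smaller"`` (the smaller set) or ``"reference"`` (the set
    named by ``reference``).
    """
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both sets are empty")
    inter = len(a & b)
    if denominator == "union":
        denom = len(a | b)
    elif denominator == "smaller":
        denom = min(len(a), len(b)) or max(len(a), len(b))
    elif denominator == "reference":
        denom = len(a if reference == "a" else b)
        if denom == 0:
            raise ValueError("reference set is empty")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * inter / denom
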