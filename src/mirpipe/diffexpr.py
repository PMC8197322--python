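"""Moderated-t differential expression with Storey q-value FDR estimation.

The two-group moderated t-statistic shrinks each assay's residual
variance s_g^2 (pooled, d_g = n1 + n2 - 2 df) towards a prior variance
s_0^2 with prior degrees of freedom d_0, both estimated from the whole
panel by the method of moments on log s_g^2 (the empirical-Bayes
hierarchical model in which s_g^2 follows a scaled F distribution under
an inverse-chi-square prior).  The posterior variance is

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and t_g = effect_g / (s~_g sqrt(1/n1 + 1/n2)) is referred to a t
distribution on d_0 + d_g degrees of freedom.  Because the test runs on
dCt values (a log2 scale), the effect is directly the log2 fold change.

The false discovery rate is estimated with the fixed-lambda q-value
point estimator: pi0 = #{p > lambda} / (m (1 - lambda)) capped at 1,
q_(i) = min_{j>=i} pi0 * m * p_(j) / j over the sorted p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .normalization import NormalizedExpression, fold_change
from .qpcr_io import GroupDesign


@dataclass
class EBayesParams:
    """Hyperparameters of the variance prior plus the FDR tuning constant."""

    d0: float          # prior degrees of freedom (may be inf)
    s0_sq: float       # prior variance, cycles^2
    lambda_: float = 0.5
    pi0: float | None = None

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class EBayesFit:
    """Per-assay moderated-t results plus the fitted prior."""

    table: pd.DataFrame          # effect, stderr, sg_sq, dg, s_tilde_sq, t_mod, df_total, p
    params: EBayesParams


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _moment_fit_fdist(sg_sq: np.ndarray, dg: float):
    """Moment estimation of (d0, s0_sq) from scaled-F distributed variances.

    Works on z = log(sg_sq): under the model z - log(s0_sq) is distributed
    as the difference of two log-chi-square variables, whose mean and
    variance involve digamma/trigamma functions of dg/2 and d0/2.
    """
    if np.any(sg_sq <= 0) or not np.all(np.isfinite(sg_sq)):
        raise ValueError(
            "residual variances must be finite and positive for moment "
            "estimation (zero-variance assays cannot be shrunk)"
        )
    z = np.log(sg_sq)
    e = z - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    emean = e.mean()
    n = len(e)
    evar = np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, dg / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def fit_ebayes(
    delta_ct: pd.DataFrame,
    design: GroupDesign,
    prior_df: float | None = None,
) -> EBayesFit:
    """Fit the two-group moderated t on a dCt matrix (assays x samples).

    ``prior_df`` overrides the estimated d0 (0 gives the ordinary pooled
    two-sample t; ``math.inf`` fixes the variance at the prior).
    """
    ref_s = [s for s in design.samples(design.reference) if s in delta_ct.columns]
    test_s = [s for s in design.samples(design.test) if s in delta_ct.columns]
    n1, n2 = len(ref_s), len(test_s)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >=2 samples")
    if len(delta_ct) < 2:
        raise ValueError("need >=2 assays to moderate variances")
    dg = n1 + n2 - 2
    if dg <= 0:
        raise ValueError("zero residual degrees of freedom")

    a = delta_ct[ref_s].to_numpy(dtype=float)
    b = delta_ct[test_s].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("dCt matrix contains undetected wells; filter first")
    # effect oriented as log2 fold change: mean(reference) - mean(test),
    # positive when expression is higher in the test group
    effect = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    sg_sq = ss / dg

    d0, s0_sq = _moment_fit_fdist(sg_sq, dg)
    if prior_df is not None:
        d0 = float(prior_df)

    if math.isinf(d0):
        s_tilde_sq = np.full_like(sg_sq, s0_sq)
        df_total = math.inf
    elif d0 == 0:
        s_tilde_sq = sg_sq.copy()
        df_total = float(dg)
    else:
        s_tilde_sq = (d0 * s0_sq + dg * sg_sq) / (d0 + dg)
        df_total = float(d0 + dg)

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    t_mod = effect / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "effect": effect,
            "sg_sq": sg_sq,
            "dg": dg,
            "s_tilde_sq": s_tilde_sq,
            "stderr": se,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
        },
        index=delta_ct.index,
    )
    table.index.name = "assay"
    return EBayesFit(table=table, params=EBayesParams(d0=d0, s0_sq=s0_sq))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(p, lambda_: float = 0.5):
    """Fixed-lambda q-value estimation.

    pi0 = #{p_i > lambda} / (m (1 - lambda)), capped at 1;
    q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the sorted p-values, with
    tied p-values sharing a q-value.  Returns ``(q, pi0)`` with q in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = np.sum(p > lambda_) / (m * (1.0 - lambda_))
    pi0 = min(pi0, 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    # ties share the q of their common rank block (step-up already
    # guarantees equal values for equal p, but enforce exactly)
    ps = p[order]
    for val in np.unique(ps[:-1][ps[:-1] == ps[1:]]):
        q[p == val] = q[p == val].min()
    return q, float(pi0)


# ---------------------------------------------------------------------------
# top-level differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    norm: NormalizedExpression,
    design: GroupDesign,
    fdr_level: float = 0.10,
    lambda_: float = 0.5,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t + q-value differential expression on normalized data.

    Returns one row per fully observed assay with fold change, moderated
    t, p, q and a significance call at ``fdr_level`` (q <= level),
    partitioned by direction (FC > 1 increased, FC < 1 decreased in the
    test condition).
    """
    d = norm.delta_ct
    complete = d.notna().all(axis=1)
    d = d.loc[complete]
    if len(d) == 0:
        raise ValueError("no assay has complete data in both groups")
    fit = fit_ebayes(d, design, prior_df=prior_df)
    fc = fold_change(norm, design).loc[d.index]
    q, pi0 = storey_qvalues(fit.table["p"].to_numpy(), lambda_=lambda_)
    out = pd.DataFrame(
        {
            "fc": fc["fc"],
            "log2fc": fc["log2fc"],
            "t_mod": fit.table["t_mod"],
            "df": fit.table["df_total"],
            "p": fit.table["p"],
            "q": q,
        },
        index=d.index,
    )
    out["significant"] = out["q"] <= fdr_level
    out["direction"] = np.where(out["fc"] > 1.0, "increased",
                                np.where(out["fc"] < 1.0, "decreased", "flat"))
    out.index.name = "assay"
    out.attrs["pi0"] = pi0
    out.attrs["d0"] = fit.params.d0
    out.attrs["s0_sq"] = fit.params.s0_sq
    out.attrs["fdr_level"] = fdr_level
    return out.sort_values("p")
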