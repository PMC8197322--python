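"""Delta-Ct normalization, fold changes, sample pooling and precision summaries.

Expression is normalized against the per-sample reference profile (mean Ct
of the selected reference miRNAs): dCt = Ct - reference.  Relative
quantities are 2^-dCt, so a one-cycle drop in dCt doubles the estimated
abundance.  Fold changes are oriented so that FC > 1 means higher
expression in the *test* condition of the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hkg import geometric_mean_reference
from .qpcr_io import OK, CtMatrix, GroupDesign


@dataclass
class NormalizedExpression:
    """Per-assay, per-sample normalized expression.

    ``delta_ct`` is Ct minus the per-sample reference (cycles, NaN where
    the well was not detected); ``rel_quantity`` is 2^-delta_ct.
    """

    delta_ct: pd.DataFrame
    rel_quantity: pd.DataFrame
    hkgs: list
    reference_profile: pd.Series

    @property
    def assay_ids(self) -> list:
        return list(self.delta_ct.index)

    @property
    def sample_ids(self) -> list:
        return list(self.delta_ct.columns)


def normalize(m: CtMatrix, hkgs) -> NormalizedExpression:
    """Normalize a Ct matrix against the mean-Ct profile of ``hkgs``."""
    hkgs = list(hkgs)
    reference = geometric_mean_reference(m, hkgs)
    delta_ct = m.ct.sub(reference, axis=1)
    rel_quantity = np.power(2.0, -delta_ct)
    return NormalizedExpression(delta_ct, rel_quantity, hkgs, reference)


def fold_change(norm: NormalizedExpression, design: GroupDesign) -> pd.DataFrame:
    """Per-assay fold change between the contrast groups.

    log2FC = mean(dCt, reference group) - mean(dCt, test group); because
    lower dCt means higher abundance, log2FC > 0 (FC > 1) indicates higher
    expression in the test group.  Assays lacking data in either group are
    flagged and carry NaN.
    """
    ref_s = [s for s in design.samples(design.reference) if s in norm.sample_ids]
    test_s = [s for s in design.samples(design.test) if s in norm.sample_ids]
    if len(ref_s) < 2 or len(test_s) < 2:
        raise ValueError("each contrast group needs >=2 samples with data")
    d = norm.delta_ct
    mean_ref = d[ref_s].mean(axis=1)
    mean_test = d[test_s].mean(axis=1)
    defined = d[ref_s].notna().any(axis=1) & d[test_s].notna().any(axis=1)
    log2fc = (mean_ref - mean_test).where(defined)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.power(2.0, log2fc),
            "n_reference": d[ref_s].notna().sum(axis=1),
            "n_test": d[test_s].notna().sum(axis=1),
            "defined": defined,
        },
        index=d.index,
    )
    out.index.name = "assay"
    return out


def pool_samples(m: CtMatrix, members, name: str, condition: str | None = None) -> CtMatrix:
    """Append an in-silico pooled sample (equal-parts mixture of ``members``).

    Pooling acts on the linear scale: the pooled relative quantity is the
    arithmetic mean of the members' 2^-Ct values, and the pooled Ct its
    -log2.  All members must be detected for every assay (detection-filter
    first).
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("pooling needs at least 2 member samples")
    missing = [s for s in members if s not in m.sample_ids]
    if missing:
        raise ValueError(f"member samples not in matrix: {missing}")
    if name in m.sample_ids:
        raise ValueError(f"sample id {name!r} already exists")
    sub_status = m.status[members]
    if not (sub_status.to_numpy() == OK).all():
        bad = sub_status.index[(sub_status != OK).any(axis=1)][0]
        raise ValueError(
            f"assay {bad!r} is not detected in every pooled member; "
            "apply the detection filter before pooling"
        )
    linear = np.power(2.0, -m.ct[members])
    pooled_ct = -np.log2(linear.mean(axis=1))
    out = m.copy()
    out.ct[name] = pooled_ct
    out.status[name] = OK
    meta_row = {
        "condition": condition or m.meta.loc[members[0], "condition"],
        "cell_line": "pooled",
        "batch": m.meta.loc[members[0], "batch"],
        "pooled": 1,
    }
    out.meta.loc[name] = meta_row
    return CtMatrix(out.ct, out.status, out.meta)


@dataclass
class PrecisionSummary:
    """Percent deviation of replicate levels from the pooled-group mean."""

    per_assay_deviation: pd.Series  # %
    median: float                   # %
    iqr: tuple                      # (25th, 75th percentile), %
    method: str = "sd"

    def __post_init__(self) -> None:
        lo, hi = self.iqr
        assert lo <= self.median <= hi


def precision_summary(
    levels: pd.DataFrame,
    pooled_mean: pd.Series,
    method: str = "sd",
) -> PrecisionSummary:
    """Summarize replicate dispersion around the pooled mean, per assay.

    ``levels`` holds linear expression levels (rows = assays, columns =
    replicate measurements from individual lines/experiments) and
    ``pooled_mean`` the pooled-sample mean level per assay.  The default
    deviation is SD(replicates)/pooled_mean x 100; ``method="mad"``
    uses the mean absolute deviation from the pooled mean instead.  Only
    fully amplified assays (no missing replicate) enter the summary.
    """
    levels = levels.loc[levels.notna().all(axis=1)]
    if levels.shape[1] < 2:
        raise ValueError("need >=2 replicate levels per assay")
    pooled = pooled_mean.reindex(levels.index)
    if pooled.isna().any() or (pooled == 0).any():
        raise ValueError("every assay needs a non-zero pooled mean")
    if method == "sd":
        dev = levels.std(axis=1, ddof=1) / pooled * 100.0
    elif method == "mad":
        dev = levels.sub(pooled, axis=0).abs().mean(axis=1) / pooled * 100.0
    else:
        raise ValueError(f"unknown method {method!r}")
    dev = dev.abs()
    return PrecisionSummary(
        per_assay_deviation=dev,
        median=float(dev.median()),
        iqr=(float(dev.quantile(0.25)), float(dev.quantile(0.75))),
        method=method,
    )
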