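"""Reading, validation and writing of cycle-threshold (Ct) matrices.

A Ct matrix is the central input of the pipeline: one row per miRNA assay,
one column per sample, each cell the PCR cycle at which the assay's
fluorescence crossed threshold (lower Ct = higher abundance).  Failed
amplification is recorded distinctly from a physically missing well: array
exports conflate the two, but both must be excluded when requiring that an
assay was detected in every sample.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Cell status codes.  ``ct`` holds NaN wherever status != OK.
OK = 0
NOT_AMPLIFIED = 1  # reaction ran but never crossed threshold ("Undetermined")
MISSING = 2        # no measurement for this well at all

NOT_AMPLIFIED_TOKEN = "Undetermined"
MISSING_TOKEN = "NA"

#: PCR run length in cycles; a finite Ct can never exceed it.
CT_MAX_CYCLES = 40.0


class CtValidationError(ValueError):
    """Raised when a Ct matrix violates a structural invariant."""


class CtParseError(ValueError):
    """Raised when a Ct file cell cannot be interpreted."""


class EmptyPanelError(ValueError):
    """Raised when a filter removes every assay from the panel."""


@dataclass
class CtMatrix:
    """miRNA-assay x sample matrix of cycle-threshold values.

    Attributes
    ----------
    ct : pandas.DataFrame
        Float Ct values (cycles), index = assay ids, columns = sample ids.
        NaN wherever the well did not yield a finite Ct.
    status : pandas.DataFrame
        Integer cell status (OK / NOT_AMPLIFIED / MISSING), same shape.
    meta : pandas.DataFrame
        Per-sample metadata indexed by sample id with columns
        ``condition``, ``cell_line``, ``batch`` and ``pooled`` (0/1).
    """

    ct: pd.DataFrame
    status: pd.DataFrame = None
    meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        if self.status is None:
            status = np.where(np.isfinite(self.ct.to_numpy()), OK, NOT_AMPLIFIED)
            self.status = pd.DataFrame(
                status, index=self.ct.index, columns=self.ct.columns
            )
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "condition": "unknown",
                    "cell_line": "unknown",
                    "batch": "unknown",
                    "pooled": 0,
                },
                index=self.ct.columns,
            )
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask of wells with a finite Ct."""
        return self.status == OK

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.ct.copy(), self.status.copy(), self.meta.copy())

    def subset_assays(self, assays) -> "CtMatrix":
        assays = list(assays)
        return CtMatrix(
            self.ct.loc[assays].copy(),
            self.status.loc[assays].copy(),
            self.meta.copy(),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.ct.index
        cols = self.ct.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise CtValidationError(f"duplicate assay id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise CtValidationError(f"duplicate sample id: {dup!r}")
        if self.status.shape != self.ct.shape:
            raise CtValidationError("status and ct shapes differ")
        vals = self.ct.to_numpy()
        ok = self.status.to_numpy() == OK
        if np.isnan(vals[ok]).any():
            raise CtValidationError("NaN Ct in a well flagged as detected")
        finite = vals[ok]
        if finite.size and (np.any(finite <= 0) or np.any(finite > CT_MAX_CYCLES)):
            raise CtValidationError(
                f"finite Ct values must lie in (0, {CT_MAX_CYCLES}]"
            )
        if not np.isnan(vals[~ok]).all():
            raise CtValidationError("non-detected wells must carry NaN Ct")
        if not self.meta.index.equals(cols):
            missing = set(cols) - set(self.meta.index)
            if missing:
                raise CtValidationError(f"samples without metadata: {sorted(missing)}")
            self.meta = self.meta.loc[cols]
        cond = self.meta["condition"].astype(str)
        if (cond.str.len() == 0).any() or cond.isna().any():
            bad = self.meta.index[(cond.str.len() == 0) | cond.isna()][0]
            raise CtValidationError(f"sample {bad!r} has an empty condition label")


@dataclass
class GroupDesign:
    """Two-group contrast: which samples belong to which condition.

    ``contrast`` is an ordered (reference, test) pair; fold changes > 1
    mean higher expression in the *test* condition.
    """

    condition_of: dict
    contrast: tuple

    def __post_init__(self) -> None:
        ref, test = self.contrast
        for name in (ref, test):
            if self.n_samples(name) < 2:
                raise CtValidationError(
                    f"contrast condition {name!r} has fewer than 2 samples"
                )

    @classmethod
    def from_meta(cls, meta: pd.DataFrame, contrast: tuple) -> "GroupDesign":
        return cls(dict(meta["condition"].astype(str)), tuple(contrast))

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of.items() if c == condition]

    def n_samples(self, condition: str) -> int:
        return len(self.samples(condition))

    @property
    def reference(self) -> str:
        return self.contrast[0]

    @property
    def test(self) -> str:
        return self.contrast[1]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_ASSAY_NAME_HINTS = ("hsa-", "mir-", "mir", "let-7")


def _looks_like_assay_name(token: str) -> bool:
    t = str(token).strip().lower()
    return t.startswith(("hsa-", "let-7")) or "mir" in t


def read_ct_matrix(path, dialect: str | None = None, meta: pd.DataFrame | None = None) -> CtMatrix:
    """Read a delimited Ct matrix (assays in rows, samples in columns).

    ``"Undetermined"`` cells map to the not-amplified marker and
    ``"NA"``/empty cells to the missing-well marker.  A header row that
    looks like miRNA assay names (transposed input) is rejected rather
    than silently fixed.
    """
    sep = _separator(path, dialect)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    header_tokens = first.split(sep)[1:]
    if len(set(header_tokens)) != len(header_tokens):
        dup = next(h for h in header_tokens if header_tokens.count(h) > 1)
        raise CtValidationError(f"duplicate sample id: {dup!r}")
    raw = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str,
                      keep_default_na=False, encoding="utf-8")
    raw.columns = header_tokens
    header = list(raw.columns)
    if header and sum(_looks_like_assay_name(h) for h in header) > len(header) / 2:
        raise CtValidationError(
            "header row looks like assay names; the matrix appears transposed "
            "(expected assays in rows, samples in columns)"
        )
    ct = np.full(raw.shape, np.nan)
    status = np.full(raw.shape, OK, dtype=int)
    arr = raw.to_numpy()
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cell = str(arr[i, j]).strip()
            if cell == NOT_AMPLIFIED_TOKEN:
                status[i, j] = NOT_AMPLIFIED
            elif cell in ("", MISSING_TOKEN, "nan"):
                status[i, j] = MISSING
            else:
                try:
                    ct[i, j] = float(cell)
                except ValueError:
                    raise CtParseError(
                        f"cannot parse cell at assay {raw.index[i]!r}, "
                        f"sample {header[j]!r}: {cell!r}"
                    ) from None
    m = CtMatrix(
        pd.DataFrame(ct, index=raw.index.astype(str), columns=header),
        pd.DataFrame(status, index=raw.index.astype(str), columns=header),
        meta,
    )
    return m


def write_ct_matrix(m: CtMatrix, path, dialect: str | None = None) -> None:
    """Write a Ct matrix, preserving the not-amplified/missing tokens."""
    sep = _separator(path, dialect)
    out = m.ct.map(lambda v: "" if np.isnan(v) else format(v, ".12g"))
    out = out.where(m.status != NOT_AMPLIFIED, NOT_AMPLIFIED_TOKEN)
    out = out.where(m.status != MISSING, MISSING_TOKEN)
    out.to_csv(path, sep=sep, encoding="utf-8")


def read_sample_metadata(path, dialect: str | None = None) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, condition, cell_line, batch, pooled)."""
    sep = _separator(path, dialect)
    meta = pd.read_csv(path, sep=sep, index_col=0, dtype=str, encoding="utf-8")
    if "pooled" in meta.columns:
        meta["pooled"] = meta["pooled"].astype(int)
    else:
        meta["pooled"] = 0
    for col in ("condition", "cell_line", "batch"):
        if col not in meta.columns:
            meta[col] = "unknown"
    return meta


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id", encoding="utf-8")


def _separator(path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


# ---------------------------------------------------------------------------
# detection rule
# ---------------------------------------------------------------------------

@dataclass
class DetectionReport:
    """Outcome of the all-samples detection rule."""

    kept: list = field(default_factory=list)
    dropped: list = field(default_factory=list)
    detected_samples: pd.Series = None  # per-assay count of detected samples
    ct_max: float = CT_MAX_CYCLES

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def detection_filter(m: CtMatrix, ct_max: float = CT_MAX_CYCLES):
    """Keep only assays with a finite Ct <= ``ct_max`` in *every* sample.

    Returns the filtered matrix and a :class:`DetectionReport`.  Raises
    :class:`EmptyPanelError` if nothing survives.
    """
    detected = m.detected & (m.ct <= ct_max)
    counts = detected.sum(axis=1)
    keep = counts == len(m.sample_ids)
    kept = [a for a, k in zip(m.assay_ids, keep) if k]
    dropped = [a for a, k in zip(m.assay_ids, keep) if not k]
    if not kept:
        raise EmptyPanelError(
            f"no assay is detected (Ct <= {ct_max}) in all {len(m.sample_ids)} samples"
        )
    report = DetectionReport(kept=kept, dropped=dropped,
                             detected_samples=counts, ct_max=ct_max)
    return m.subset_assays(kept), report


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path, format: str | None = None) -> None:
    """Write a result table as TSV or JSON, loss-free to >=12 significant digits."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    fmt = format or ("json" if str(path).lower().endswith(".json") else "tsv")
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format="%.17g",
                     encoding="utf-8")
    elif fmt == "json":
        records = json.loads(table.to_json(orient="records", double_precision=15))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown result format {fmt!r}")


def read_results(path, format: str | None = None) -> pd.DataFrame:
    fmt = format or ("json" if str(path).lower().endswith(".json") else "tsv")
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", encoding="utf-8")
    with open(path, encoding="utf-8") as fh:
        return pd.DataFrame(json.load(fh))
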