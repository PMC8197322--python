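"""Synthetic data generators with explicit ground truth.

Every generator is a pure function of a truth object and a seed, so any
pipeline stage can be tested as a parameter-recovery problem: the panel
generator writes designed fold changes into the Ct matrix additively as
-log2(FC) for the test group, which the delta-Ct / fold-change stack
recovers exactly in the noiseless limit; the clonogenic generator draws
binomial colony counts at designed plating efficiencies; the
dose-response generator draws multinomial flow-cytometry quadrant counts
around a designed 4PL curve.

The default panel emulates a 111-assay miRNA panel measured on two
groups of three cell lines, with a designed block of stable reference
assays, a designed block of differentially expressed assays, a block of
low-expressed assays and a block with detection dropout, so that the
detection filter keeps exactly 82 of 111 assays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpcr_io import NOT_AMPLIFIED, OK, CtMatrix, GroupDesign

# default panel composition (counts sum to 111)
N_ASSAYS = 111
N_HKG = 48
N_DE_UP = 5
N_DE_DOWN = 10
N_LOW = 19
N_DROPOUT = 29

#: per-well technical Ct noise (cycles); emulates the precision of a
#: preamplified TaqMan panel after averaging technical replicates
DEFAULT_NOISE_SD = 0.005
#: per-batch loading/RT shift (cycles), shared by all assays of a sample
#: and by the condition-paired samples processed in the same batch
DEFAULT_SAMPLE_EFFECT_SD = 0.04


@dataclass
class PanelTruth:
    """Ground truth of a synthetic Ct panel."""

    n_assays: int = N_ASSAYS
    hkg_ids: list = field(default_factory=list)
    de_spec: dict = field(default_factory=dict)   # assay -> true FC (test vs ref)
    baseline_ct: dict = field(default_factory=dict)
    dropout_cells: dict = field(default_factory=dict)  # assay -> [sample ids]
    noise_sd: float = DEFAULT_NOISE_SD
    sample_effect_sd: float = DEFAULT_SAMPLE_EFFECT_SD
    dropout_ct: float = 40.0
    conditions: tuple = ("parental", "p53KO")
    samples_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.hkg_ids) & set(self.de_spec):
            raise ValueError("an assay cannot be both a designed HKG and DE")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.dropout_ct > 40.0:
            raise ValueError("dropout_ct cannot exceed the 40-cycle run length")

    @property
    def sample_ids(self) -> list:
        ref, test = self.conditions
        return [f"{ref}-{i+1}" for i in range(self.samples_per_group)] + [
            f"{test}-{i+1}" for i in range(self.samples_per_group)
        ]

    def design(self) -> GroupDesign:
        ref, test = self.conditions
        cond = {s: (ref if s.startswith(ref) else test) for s in self.sample_ids}
        return GroupDesign(cond, (ref, test))

    def to_json(self, path) -> None:
        payload = {
            k: (list(v) if isinstance(v, (set, tuple)) else v)
            for k, v in vars(self).items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "PanelTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["conditions"] = tuple(payload["conditions"])
        return cls(**payload)


def default_panel_truth(seed: int = 0) -> PanelTruth:
    """The default 111-assay panel design.

    48 stable reference assays (Ct 18-28), 5 increased (FC 1.3) and 10
    decreased (FC 0.60-0.85) assays, 19 stable but low-expressed assays
    (Ct 31-36, above the reference expression cap) and 29 assays with
    designed detection dropout in at least one sample.
    """
    rng = np.random.default_rng(seed)
    ids = [f"sim-miR-{i:03d}" for i in range(1, N_ASSAYS + 1)]
    hkg_ids = ids[:N_HKG]
    up_ids = ids[N_HKG:N_HKG + N_DE_UP]
    down_ids = ids[N_HKG + N_DE_UP:N_HKG + N_DE_UP + N_DE_DOWN]
    low_ids = ids[N_HKG + N_DE_UP + N_DE_DOWN:N_HKG + N_DE_UP + N_DE_DOWN + N_LOW]
    drop_ids = ids[-N_DROPOUT:]

    de_spec = {a: 1.3 for a in up_ids}
    for a, fc in zip(down_ids, np.linspace(0.60, 0.85, N_DE_DOWN)):
        de_spec[a] = round(float(fc), 4)

    baseline = {}
    for a in hkg_ids:
        baseline[a] = float(rng.uniform(18.0, 28.0))
    for a in up_ids + down_ids:
        baseline[a] = float(rng.uniform(20.0, 28.0))
    for a in low_ids:
        baseline[a] = float(rng.uniform(31.0, 36.0))
    for a in drop_ids:
        baseline[a] = float(rng.uniform(36.0, 39.5))

    truth = PanelTruth(hkg_ids=hkg_ids, de_spec=de_spec, baseline_ct=baseline,
                       seed=seed)
    samples = truth.sample_ids
    dropout_cells = {}
    for a in drop_ids:
        k = int(rng.integers(1, len(samples) + 1))
        chosen = rng.choice(samples, size=k, replace=False)
        dropout_cells[a] = sorted(chosen.tolist())
    truth.dropout_cells = dropout_cells
    return truth


def generate_ct_matrix(truth: PanelTruth, seed: int | None = None):
    """Draw a Ct matrix from a panel truth; returns ``(CtMatrix, truth)``.

    Ct = baseline + per-sample effect + group effect (-log2 FC for test
    samples of designed-DE assays) + Gaussian noise; wells designed as
    dropout, or whose Ct exceeds ``dropout_ct``, become not-amplified.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    samples = truth.sample_ids
    assays = list(truth.baseline_ct)
    if len(assays) != truth.n_assays:
        raise ValueError("baseline_ct must cover every assay")
    ref, test = truth.conditions
    in_test = np.array([s.startswith(test) for s in samples])

    # loading/RT shifts are batch effects: the k-th sample of each
    # condition is processed in the same batch and shares the shift
    # (delta-Ct normalization removes them; they carry the shared
    # variation that the reference-correlation criterion relies on)
    batch_eff = rng.normal(0.0, truth.sample_effect_sd,
                           size=truth.samples_per_group)
    sample_eff = np.concatenate([batch_eff, batch_eff])
    ct = np.empty((len(assays), len(samples)))
    for i, a in enumerate(assays):
        row = truth.baseline_ct[a] + sample_eff
        fc = truth.de_spec.get(a)
        if fc is not None:
            row = row - math.log2(fc) * in_test
        ct[i] = row + rng.normal(0.0, truth.noise_sd, size=len(samples))

    status = np.full(ct.shape, OK, dtype=int)
    for a, cells in truth.dropout_cells.items():
        i = assays.index(a)
        for s in cells:
            status[i, samples.index(s)] = NOT_AMPLIFIED
    status[ct > truth.dropout_ct] = NOT_AMPLIFIED
    ct[status != OK] = np.nan
    ct[status == OK] = np.clip(ct[status == OK], 1e-6, 40.0)

    lines = {ref: ["polyclonal", "clonal", "cas9"],
             test: ["clone1", "clone7", "clone14"]}
    meta = pd.DataFrame(
        {
            "condition": [ref if not t else test for t in in_test],
            "cell_line": [
                lines.get(ref, ["?"] * 3)[i % 3] if not t else
                lines.get(test, ["?"] * 3)[i % 3]
                for i, t in enumerate(in_test)
            ],
            "batch": [f"batch{(i % truth.samples_per_group) + 1}"
                      for i in range(len(samples))],
            "pooled": 0,
        },
        index=samples,
    )
    m = CtMatrix(
        pd.DataFrame(ct, index=assays, columns=samples),
        pd.DataFrame(status, index=assays, columns=samples),
        meta,
    )
    return m, truth


# ---------------------------------------------------------------------------
# treatment-response assay truth
# ---------------------------------------------------------------------------

def _default_true_pe() -> dict:
    # plating efficiencies consistent with counted colonies of ~95/500 and
    # ~53/750 (control line) vs ~102/500 and ~88/750 (knockout line)
    return {
        "parental": {0.0: 0.19, 2.0: 53.0 / 750.0},
        "p53KO": {0.0: 0.204, 2.0: 88.0 / 750.0},
    }


def _default_true_4pl() -> dict:
    # midpoints match the working IC50 concentrations of the four agents
    return {
        "cisplatin": {"bottom": 5.0, "top": 97.0, "ic50": 8.0, "hill": 1.5},
        "5-FU": {"bottom": 5.0, "top": 97.0, "ic50": 19.0, "hill": 1.5},
        "4-hydroxytamoxifen": {"bottom": 5.0, "top": 97.0, "ic50": 7.8, "hill": 1.5},
        "endoxifen": {"bottom": 5.0, "top": 97.0, "ic50": 6.7, "hill": 1.5},
    }


@dataclass
class AssayTruth:
    """Ground truth for clonogenic and dose-response simulations."""

    true_pe: dict = field(default_factory=_default_true_pe)
    true_4pl: dict = field(default_factory=_default_true_4pl)
    events_per_replicate: int | float = 2000
    early_fraction: float = 0.5   # share of non-viable events in early apoptosis
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, by_dose in self.true_pe.items():
            for dose, p in by_dose.items():
                if not 0 < p < 1:
                    raise ValueError(f"true PE for {cond}@{dose} outside (0,1)")
        for drug, p in self.true_4pl.items():
            if p["ic50"] <= 0:
                raise ValueError(f"IC50 for {drug} must be > 0")


def generate_clonogenic(
    truth: AssayTruth,
    plated: dict | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binomial colony counts at the designed plating efficiencies.

    ``plated`` maps dose (Gy) to cells plated per well (default 500 at
    0 Gy, 750 at 2 Gy).
    """
    plated = plated if plated is not None else {0.0: 500, 2.0: 750}
    if any(n <= 0 for n in plated.values()):
        raise ValueError("cells plated must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for cond, by_dose in truth.true_pe.items():
        for dose, pe in by_dose.items():
            n = int(plated[dose])
            colonies = rng.binomial(n, pe, size=n_replicates)
            for r, c in enumerate(colonies, start=1):
                rows.append((cond, dose, n, int(c), r))
    return pd.DataFrame(rows, columns=["sample", "dose_gy", "cells_plated",
                                       "colonies", "replicate"])


def generate_dose_response(
    truth: AssayTruth,
    drug: str,
    doses=(1.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    n_replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multinomial flow-cytometry quadrant percentages around a 4PL curve.

    The true viable percentage follows the designed 4PL; the non-viable
    remainder splits into early/late apoptosis by ``early_fraction``.
    ``events_per_replicate=math.inf`` returns the noiseless expectation.
    A vehicle record (dose 0) is included.
    """
    doses = [float(d) for d in doses]
    if len(set(doses)) < 5:
        raise ValueError("need >=5 distinct doses")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be > 0")
    p4 = truth.true_4pl[drug]
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    def true_viable(dose: float | None) -> float:
        if dose is None:  # vehicle: zero-dose limit of the curve
            return p4["top"]
        return p4["bottom"] + (p4["top"] - p4["bottom"]) / (
            1.0 + (dose / p4["ic50"]) ** p4["hill"]
        )

    rows = []
    for dose, is_vehicle in [(None, True)] + [(d, False) for d in doses]:
        v = np.clip(true_viable(dose) / 100.0, 0.0, 1.0)
        dead = 1.0 - v
        probs = [v, dead * truth.early_fraction, dead * (1 - truth.early_fraction)]
        for r in range(1, n_replicates + 1):
            if math.isinf(truth.events_per_replicate):
                pct = [100.0 * q for q in probs]
            else:
                counts = rng.multinomial(int(truth.events_per_replicate), probs)
                pct = 100.0 * counts / truth.events_per_replicate
            rows.append((drug, 0.0 if is_vehicle else dose, pct[0], pct[1],
                         pct[2], is_vehicle, r))
    return pd.DataFrame(rows, columns=["drug", "dose_um", "viable_pct",
                                       "early_pct", "late_pct", "vehicle",
                                       "replicate"])
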