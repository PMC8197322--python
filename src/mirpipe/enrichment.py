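"""miRNA-target lookup and hypergeometric pathway over-representation.

A query gene set (the validated mRNA targets of one or more miRNAs) is
tested for over-representation in each pathway of a pathway database.
With a universe of M genes, a pathway of K genes and a query of n genes
drawn from the universe, the upper-tail hypergeometric probability of an
overlap at least as large as observed is the enrichment p-value; the
Benjamini-Hochberg correction (default) controls the FDR across
pathways.

The bundled databases are *synthetic* stand-ins with realistic set sizes
(see :func:`synthetic_target_db`); they are reimplementations of a
target/pathway lookup flow, not snapshots of any live database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TargetDB:
    """Validated miRNA -> target-gene map."""

    mirna_to_genes: dict
    source: str = "unknown"
    version: str = "0"

    def __post_init__(self) -> None:
        clean = {}
        for mirna, genes in self.mirna_to_genes.items():
            genes = {str(g).upper() for g in genes}
            if not genes:
                raise ValueError(f"empty target set for {mirna!r}")
            clean[mirna] = genes
        self.mirna_to_genes = clean

    @classmethod
    def from_tsv(cls, path) -> "TargetDB":
        """Read a (mirna, gene[, evidence]) TSV; '#key: value' headers set
        source/version."""
        source, version = "unknown", "0"
        with open(path, encoding="utf-8") as fh:
            lines = fh.readlines()
        rows = []
        for line in lines:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    if key.strip() == "source":
                        source = val.strip()
                    elif key.strip() == "version":
                        version = val.strip()
                continue
            if not line or line.startswith("mirna\t"):
                continue
            parts = line.split("\t")
            rows.append((parts[0], parts[1]))
        db: dict = {}
        for mirna, gene in rows:
            db.setdefault(mirna, set()).add(gene)
        return cls(db, source=source, version=version)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#source: {self.source}\n#version: {self.version}\n")
            fh.write("mirna\tgene\n")
            for mirna in sorted(self.mirna_to_genes):
                for gene in sorted(self.mirna_to_genes[mirna]):
                    fh.write(f"{mirna}\t{gene}\n")


@dataclass
class PathwayDB:
    """Pathway -> gene-set map with an explicit gene universe."""

    pathway_to_genes: dict
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        clean = {}
        for pw, genes in self.pathway_to_genes.items():
            genes = {str(g).upper() for g in genes}
            if not genes:
                raise ValueError(f"empty gene set for pathway {pw!r}")
            clean[pw] = genes
        self.pathway_to_genes = clean
        self.universe = {str(g).upper() for g in self.universe}
        all_genes = set().union(*clean.values()) if clean else set()
        if not self.universe:
            self.universe = all_genes
        elif not all_genes <= self.universe:
            raise ValueError("pathway genes missing from the universe")

    @classmethod
    def from_tsv(cls, path) -> "PathwayDB":
        df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
        db: dict = {}
        for pw, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            db.setdefault(str(pw), set()).add(str(gene))
        return cls(db)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pathway\tgene\n")
            for pw in sorted(self.pathway_to_genes):
                for gene in sorted(self.pathway_to_genes[pw]):
                    fh.write(f"{pw}\t{gene}\n")


def targets_of(mirnas, db: TargetDB, mode: str = "union"):
    """Validated targets of a miRNA set (union by default).

    Returns ``(genes, provenance)`` where provenance maps each gene to
    the miRNAs that target it.  Unknown miRNAs are reported with a
    warning; if none is known, an error is raised.
    """
    mirnas = list(mirnas)
    known = [m for m in mirnas if m in db.mirna_to_genes]
    missing = [m for m in mirnas if m not in db.mirna_to_genes]
    if not known:
        raise KeyError(f"none of the queried miRNAs is in the target DB: {mirnas}")
    if missing:
        warnings.warn(f"miRNAs absent from target DB ignored: {missing}",
                      stacklevel=2)
    sets = [db.mirna_to_genes[m] for m in known]
    if mode == "union":
        genes = set().union(*sets)
    elif mode == "intersection":
        genes = set.intersection(*sets)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    provenance = {
        g: sorted(m for m in known if g in db.mirna_to_genes[m]) for g in genes
    }
    return genes, provenance


def overrepresentation(
    query,
    db: PathwayDB,
    correction: str = "BH",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each pathway.

    p_raw = P(X >= k) with X ~ Hypergeom(M=|universe|, K=pathway size,
    n=|query ∩ universe|); corrected across pathways by BH (default) or
    Bonferroni.  Rows are sorted by corrected p.
    """
    query = {str(g).upper() for g in query}
    eff_query = query & db.universe
    if not eff_query:
        raise ValueError("query has no genes in the pathway universe")
    M = len(db.universe)
    n = len(eff_query)
    rows = []
    for pw, genes in db.pathway_to_genes.items():
        K = len(genes)
        k = len(eff_query & genes)
        p_raw = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append((pw, k, K, min(p_raw, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway", "uploaded_count",
                                      "pathway_size", "p_raw"])
    method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r}")
    out["p_corrected"] = multipletests(out["p_raw"], method=method)[1]
    out["p_corrected"] = np.maximum(out["p_corrected"], out["p_raw"])
    out["significant"] = out["p_corrected"] <= 0.05
    return out.sort_values(["p_corrected", "p_raw"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic fixture databases
# ---------------------------------------------------------------------------

#: target-set sizes designed into the synthetic DB (marquee regulators
#: of the p53/SLC7A11 axis are guaranteed members where biology says so)
_SYNTHETIC_TARGET_SIZES = {
    "hsa-miR-27a-3p": (431, {"TP53", "SLC7A11", "APC", "EGFR", "FOXO1", "KRAS", "MET", "PPARG"}),
    "hsa-miR-24-3p": (280, {"TP53"}),
    "hsa-miR-185-5p": (210, {"TP53"}),
    "hsa-miR-130b-3p": (190, {"ESR1", "PPARG"}),
    "hsa-miR-181a-5p": (240, {"SLC7A11"}),
    "hsa-miR-324-3p": (340, {"RPLP0", "RPL4", "RPL10", "RPS3", "RPS5", "RPS8", "WNT2B"}),
    "hsa-miR-324-5p": (150, set()),
    "hsa-miR-345-5p": (120, set()),
    "hsa-miR-328-3p": (130, {"AGO1"}),
    "hsa-miR-146b-5p": (160, {"AGO1"}),
    "hsa-miR-210-3p": (140, set()),
    "hsa-miR-140-3p": (110, {"ESR2"}),
    "hsa-miR-26a-5p": (170, {"AGO1", "ESR1"}),
    "hsa-miR-26b-5p": (150, {"SLC7A11"}),
    "hsa-miR-320a-3p": (180, {"AGO1"}),
    "hsa-miR-331-3p": (408, {"RPLP0", "RPL7A", "RPS2", "RPS3", "RPS9"}),
    "hsa-miR-30a-5p": (736, {"SLC7A11", "TP53", "NOTCH1", "IGF1R", "ESR2", "BNIP3L"}),
    "hsa-miR-1274A": (8, set()),
    "hsa-miR-1274B": (3, set()),
}

_SYNTHETIC_PATHWAYS = {
    "p53 pathway": 47,
    "p53 signalling pathway": 68,
    "Direct p53 effectors": 129,
    "Cellular responses to stress": 240,
    "Apoptosis": 155,
    "Intrinsic pathway for apoptosis": 38,
    "Cell cycle": 126,
    "Gene expression": 1118,
    "Ribosome": 137,
    "Translation": 145,
    "WNT signaling pathway": 140,
    "mTOR signaling pathway": 62,
    "TGF-beta signaling pathway": 80,
    "VEGF signaling pathway": 183,
    "Regulation of lipid metabolism by PPARalpha": 109,
    "Plasma membrane oestrogen receptor signaling": 24,
    "Validated nuclear oestrogen receptor alpha network": 64,
    "EPH-Ephrin signaling": 90,
    "Regulation of actin cytoskeleton": 120,
    "Stabilization of p53": 52,
}

_UNIVERSE_SIZE = 4000


def _synthetic_universe() -> list:
    marquee = sorted(
        {"TP53", "SLC7A11", "APC", "EGFR", "FOXO1", "KRAS", "MET", "PPARG",
         "ESR1", "ESR2", "AGO1", "WNT2B", "NOTCH1", "IGF1R", "BNIP3L",
         "RPLP0", "RPL4", "RPL7A", "RPL10", "RPS2", "RPS3", "RPS5", "RPS8",
         "RPS9"}
    )
    synthetic = [f"GENE{i:04d}" for i in range(_UNIVERSE_SIZE - len(marquee))]
    return marquee + synthetic


def synthetic_target_db(seed: int = 20210524) -> TargetDB:
    """Deterministic synthetic validated-target database.

    Target-set sizes mirror a real lookup (e.g. 431 targets for
    hsa-miR-27a-3p, 736 for hsa-miR-30a-5p); gene symbols beyond a few
    marquee genes are synthetic placeholders.
    """
    rng = np.random.default_rng(seed)
    universe = _synthetic_universe()
    db = {}
    for mirna, (size, anchors) in _SYNTHETIC_TARGET_SIZES.items():
        pool = [g for g in universe if g not in anchors]
        extra = rng.choice(len(pool), size=size - len(anchors), replace=False)
        db[mirna] = set(anchors) | {pool[i] for i in extra}
    return TargetDB(db, source="synthetic-fixture", version="1")


def synthetic_pathway_db(seed: int = 20210524) -> PathwayDB:
    """Deterministic synthetic pathway database over the same universe."""
    rng = np.random.default_rng(seed + 1)
    universe = _synthetic_universe()
    db = {}
    for pw, size in _SYNTHETIC_PATHWAYS.items():
        idx = rng.choice(len(universe), size=size, replace=False)
        db[pw] = {universe[i] for i in idx}
    return PathwayDB(db, universe=set(universe))
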