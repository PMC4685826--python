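"""Microscopy cell-count statistics and RNA-tag concordance.

Chitin-walled cells (stained with fluorescent wheatgerm agglutinin, with
DAPI confirming a nucleus) are counted on replicate filters per sample and
expressed as a percentage of total eukaryote cells/ml. The concordance
analysis regresses the chitin-cell percentage on the percentage of fungal
reads in the matching RNA-template library: ordinary least squares with the
two-sided t-test p-value (n-2 df) for the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellCountRecord",
    "Concordance",
    "filter_count_stats",
    "chitin_percent",
    "abundance_concordance",
    "read_cellcount_table",
]


@dataclass(frozen=True)
class CellCountRecord:
    sample_id: str
    chitin_replicates: tuple[float, ...]   # cells/ml per filter
    total_eukaryote_density: float         # cells/ml
    pct_rna_fungal_reads: float

    def __post_init__(self) -> None:
        if not self.chitin_replicates:
            raise ValueError(f"{self.sample_id}: need >=1 replicate filter")
        if min(self.chitin_replicates) < 0 or self.total_eukaryote_density < 0:
            raise ValueError(f"{self.sample_id}: negative density")


@dataclass(frozen=True)
class Concordance:
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def filter_count_stats(replicates: tuple[float, ...] | list[float]
                       ) -> tuple[float, float, bool]:
    """Mean and sample standard deviation (n-1) of replicate filter counts.

    Returns (mean, sd, single_replicate_flag); a single replicate yields
    sd = 0 with the flag set, since no dispersion estimate exists.
    """
    values = np.asarray(replicates, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    if (values < 0).any():
        raise ValueError("negative replicate density")
    mean = float(values.mean())
    if values.size == 1:
        return mean, 0.0, True
    return mean, float(values.std(ddof=1)), False


def chitin_percent(chitin_mean: float, total_eukaryotes: float) -> float:
    """Chitin-walled cells as percent of total eukaryote cells."""
    if total_eukaryotes <= 0:
        raise ValueError("total eukaryote density must be positive")
    return 100.0 * chitin_mean / total_eukaryotes


def abundance_concordance(records: list[CellCountRecord]) -> Concordance:
    """OLS of percent chitin-walled cells on percent RNA fungal reads."""
    if len(records) < 3:
        raise ValueError("concordance needs >= 3 samples")
    x = np.array([r.pct_rna_fungal_reads for r in records])
    y = np.array([
        chitin_percent(filter_count_stats(r.chitin_replicates)[0],
                       r.total_eukaryote_density)
        for r in records])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in RNA-read percentages")
    fit = stats.linregress(x, y)
    return Concordance(
        n=len(records),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
    )


def read_cellcount_table(path: str | Path) -> list[CellCountRecord]:
    """TSV columns: sample_id, chitin_replicates (semicolon-separated),
    total_eukaryote_density, pct_rna_fungal_reads."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "chitin_replicates", "total_eukaryote_density",
                "pct_rna_fungal_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(CellCountRecord(
            sample_id=row["sample_id"],
            chitin_replicates=tuple(
                float(v) for v in str(row["chitin_replicates"]).split(";")),
            total_eukaryote_density=float(row["total_eukaryote_density"]),
            pct_rna_fungal_reads=float(row["pct_rna_fungal_reads"]),
        ))
    return records
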