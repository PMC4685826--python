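"""Biogeographic summaries of the retained OTU clusters.

Provenance matrices aggregate per-sample read counts to any ordered subset
of the sample metadata axes (site, substrate, depth, fraction, template);
multi-site scoring lists clusters recovered from >= min_sites geographical
sites; substrate-level fungal fractions express fungal reads as a percent of
total sequencing effort per substrate; and within-cluster similarity
statistics summarize how tight the clusters are at the read level
(computed on unmasked reads with the pipeline's percent-identity measure).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cluster import OtuCluster
from .iolib import SampleTable
from .taxonomy import global_identity

__all__ = [
    "SimilarityStats",
    "provenance_matrix",
    "multi_site_clusters",
    "substrate_fungal_fraction",
    "within_cluster_similarity",
]

_GROUP_FIELDS = {
    "site": "site",
    "substrate": "substrate",
    "depth": "depth",
    "fraction": "size_fraction",
    "template": "template",
}


def provenance_matrix(
    clusters: list[OtuCluster],
    sample_table: SampleTable,
    grouping: list[str] = ("site",),
) -> pd.DataFrame:
    """Read counts per cluster per sample category.

    ``grouping`` is an ordered subset of {site, substrate, depth, fraction,
    template}; category labels join the group values with ``|``. Rows are
    cluster ids ascending, columns category labels ascending; row sums equal
    cluster read totals.
    """
    unknown = [g for g in grouping if g not in _GROUP_FIELDS]
    if unknown:
        raise ValueError(
            f"unknown grouping keys {unknown}; valid: {sorted(_GROUP_FIELDS)}")
    if not grouping:
        raise ValueError("grouping must name at least one axis")

    def category(sample_id: str) -> str:
        s = sample_table[sample_id]
        return "|".join(getattr(s, _GROUP_FIELDS[g]) for g in grouping)

    cells: dict[tuple[str, str], int] = {}
    for cluster in clusters:
        for sid, count in cluster.sample_counts.items():
            key = (cluster.cluster_id, category(sid))
            cells[key] = cells.get(key, 0) + count
    rows = sorted({c.cluster_id for c in clusters})
    cols = sorted({k[1] for k in cells})
    matrix = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (rid, cat), count in cells.items():
        matrix.loc[rid, cat] = count
    return matrix


def multi_site_clusters(matrix: pd.DataFrame, min_sites: int = 3) -> list[str]:
    """Clusters with non-zero reads in at least ``min_sites`` distinct sites.

    Expects a matrix grouped at site level (columns = site labels)."""
    if min_sites < 1:
        raise ValueError(f"min_sites must be >= 1, got {min_sites}")
    hits = (matrix > 0).sum(axis=1)
    return sorted(str(i) for i in matrix.index[hits >= min_sites])


def substrate_fungal_fraction(
    fungal_reads: dict[str, int],
    total_reads: dict[str, int],
) -> dict[str, float]:
    """Percent of each substrate's sequencing effort assigned to fungi."""
    out: dict[str, float] = {}
    for substrate, fungal in fungal_reads.items():
        total = total_reads.get(substrate, 0)
        if total <= 0:
            if fungal > 0:
                raise ValueError(
                    f"substrate {substrate!r}: {fungal} fungal reads but "
                    f"zero total reads")
            continue
        out[substrate] = 100.0 * fungal / total
    return out


@dataclass(frozen=True)
class SimilarityStats:
    """Within-cluster pairwise-identity summary across clusters."""

    per_cluster_mean: dict[str, float]
    grand_mean: float
    sem: float                      # over per-cluster means
    minimum: float
    singleton_clusters: tuple[str, ...]   # contributed 100 by convention

    def recompute_excluding_singletons(self) -> "SimilarityStats":
        kept = {k: v for k, v in self.per_cluster_mean.items()
                if k not in self.singleton_clusters}
        return _stats_from_means(kept, ())


def _stats_from_means(means: dict[str, float],
                      singletons: tuple[str, ...]) -> SimilarityStats:
    values = np.array(list(means.values()), dtype=float)
    if values.size == 0:
        return SimilarityStats({}, float("nan"), float("nan"), float("nan"),
                               singletons)
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 \
        else 0.0
    return SimilarityStats(
        per_cluster_mean=means,
        grand_mean=float(values.mean()),
        sem=sem,
        minimum=float(values.min()),
        singleton_clusters=singletons,
    )


def within_cluster_similarity(
    clusters: list[OtuCluster],
    read_sequences: dict[str, str],
) -> SimilarityStats:
    """Mean pairwise percent identity over all unordered read pairs, per
    cluster, with the grand mean, its standard error over clusters, and the
    minimum per-cluster mean.

    Pairs of identical reads contribute 100 without alignment, so the
    all-pairs mean is computed exactly at dereplicated cost: distinct
    sequence pairs are aligned once and weighted by their read multiplicity.
    Single-read clusters contribute 100 by convention and are flagged.
    """
    means: dict[str, float] = {}
    singletons: list[str] = []
    for cluster in clusters:
        seqs = [read_sequences[rid] for rid in cluster.read_ids]
        n = len(seqs)
        if n == 0:
            raise ValueError(f"cluster {cluster.cluster_id} has no reads")
        if n == 1:
            means[cluster.cluster_id] = 100.0
            singletons.append(cluster.cluster_id)
            continue
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        total_pairs = n * (n - 1) / 2
        weighted = sum(c * (c - 1) / 2 for c in counts.values()) * 100.0
        for (s1, c1), (s2, c2) in combinations(counts.items(), 2):
            weighted += c1 * c2 * global_identity(s1, s2)
        means[cluster.cluster_id] = weighted / total_pairs
    return _stats_from_means(means, tuple(singletons))
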