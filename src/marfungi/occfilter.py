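"""The multi-occurrence retention rule and its summary arithmetic.

Near-shore amplicon surveys are contaminated by passively dispersed
terrestrial spores, which show up as rare, mostly DNA-only OTU clusters.
The retention rule keeps an OTU cluster iff it occurs (>=1 read) in

* two or more samples, at least one of which is an RNA-template library, OR
* three or more samples regardless of template.

"Sample" means one nucleic-acid library: the DNA and RNA libraries from the
same water count as two samples. Occurrence is presence, not abundance —
a thousand reads in a single sample is still a single occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import OtuCluster
from .iolib import SampleTable

__all__ = [
    "OccurrenceProfile",
    "FilterSummary",
    "ExclusionCensus",
    "occurrence_profile",
    "passes_filter",
    "apply_filter",
    "exclusion_census",
    "summarize_counts",
]


@dataclass(frozen=True)
class OccurrenceProfile:
    """Distinct-sample occurrence of one OTU cluster, split by template."""

    cluster_id: str
    n_samples: int
    n_rna_samples: int
    n_dna_samples: int

    def __post_init__(self) -> None:
        if self.n_samples != self.n_rna_samples + self.n_dna_samples:
            raise ValueError(
                f"{self.cluster_id}: n_samples must equal n_rna + n_dna")
        if min(self.n_samples, self.n_rna_samples, self.n_dna_samples) < 0:
            raise ValueError(f"{self.cluster_id}: negative occurrence counts")


@dataclass(frozen=True)
class FilterSummary:
    otus_before: int
    otus_after: int
    reads_before: int
    reads_after: int

    @property
    def pct_otus_removed(self) -> float | None:
        if self.otus_before == 0:
            return None
        return 100.0 * (self.otus_before - self.otus_after) / self.otus_before

    @property
    def pct_reads_retained(self) -> float | None:
        if self.reads_before == 0:
            return None
        return 100.0 * self.reads_after / self.reads_before

    def report(self) -> dict:
        """Display form: percentages rounded to the nearest integer
        (exact values remain available through the properties)."""
        def disp(v: float | None) -> int | str:
            return "n/a" if v is None else round(v)
        return {
            "otus_before": self.otus_before,
            "otus_after": self.otus_after,
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
            "pct_otus_removed": disp(self.pct_otus_removed),
            "pct_reads_retained": disp(self.pct_reads_retained),
        }


def summarize_counts(otus_before: int, otus_after: int,
                     reads_before: int, reads_after: int) -> FilterSummary:
    """Build a :class:`FilterSummary` directly from before/after counts."""
    if otus_after > otus_before or reads_after > reads_before:
        raise ValueError("post-filter counts cannot exceed pre-filter counts")
    return FilterSummary(otus_before, otus_after, reads_before, reads_after)


def occurrence_profile(cluster: OtuCluster,
                       sample_table: SampleTable) -> OccurrenceProfile:
    """Count the distinct samples (not reads) a cluster occurs in, by template."""
    rna = dna = 0
    for sample_id, count in cluster.sample_counts.items():
        if count <= 0:
            continue
        template = sample_table[sample_id].template  # KeyError on unknown id
        if template == "RNA":
            rna += 1
        else:
            dna += 1
    return OccurrenceProfile(
        cluster_id=cluster.cluster_id,
        n_samples=rna + dna,
        n_rna_samples=rna,
        n_dna_samples=dna,
    )


def passes_filter(profile: OccurrenceProfile) -> bool:
    """The retention rule: (>=2 samples with >=1 RNA) or (>=3 samples)."""
    return (profile.n_samples >= 2 and profile.n_rna_samples >= 1) \
        or profile.n_samples >= 3


def apply_filter(
    clusters: list[OtuCluster],
    sample_table: SampleTable,
) -> tuple[list[OtuCluster], list[OtuCluster], FilterSummary]:
    """Partition clusters by the retention rule and summarize the attrition."""
    retained: list[OtuCluster] = []
    excluded: list[OtuCluster] = []
    for cluster in clusters:
        profile = occurrence_profile(cluster, sample_table)
        (retained if passes_filter(profile) else excluded).append(cluster)
    summary = FilterSummary(
        otus_before=len(clusters),
        otus_after=len(retained),
        reads_before=sum(c.total_reads for c in clusters),
        reads_after=sum(c.total_reads for c in retained),
    )
    return retained, excluded, summary


@dataclass(frozen=True)
class ExclusionCensus:
    """Breakdown of excluded clusters into the categories the attrition
    report distinguishes: singletons (one read, one sample), clusters seen
    in exactly two DNA-template samples, and everything else."""

    n_single_read_single_sample: int
    n_two_dna_samples: int
    n_other: int
    reads_single_read_single_sample: int
    reads_two_dna_samples: int
    reads_other: int
    total_cleaned_reads: int

    def share_of_total(self, reads: int) -> float | None:
        """A category's reads as a percentage of the whole cleaned effort."""
        if self.total_cleaned_reads == 0:
            return None
        return 100.0 * reads / self.total_cleaned_reads


def exclusion_census(
    excluded: list[OtuCluster],
    sample_table: SampleTable,
    total_cleaned_reads: int,
) -> ExclusionCensus:
    n_single = n_two_dna = n_other = 0
    r_single = r_two_dna = r_other = 0
    for cluster in excluded:
        profile = occurrence_profile(cluster, sample_table)
        reads = cluster.total_reads
        if profile.n_samples == 1 and reads == 1:
            n_single += 1
            r_single += reads
        elif profile.n_samples == 2 and profile.n_dna_samples == 2:
            n_two_dna += 1
            r_two_dna += reads
        else:
            n_other += 1
            r_other += reads
    return ExclusionCensus(
        n_single_read_single_sample=n_single,
        n_two_dna_samples=n_two_dna,
        n_other=n_other,
        reads_single_read_single_sample=r_single,
        reads_two_dna_samples=r_two_dna,
        reads_other=r_other,
        total_cleaned_reads=total_cleaned_reads,
    )
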