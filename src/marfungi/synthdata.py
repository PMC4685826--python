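"""Synthetic reference databases and multi-sample amplicon datasets.

The generator emulates the sampling design of a multi-site European coastal
survey: six geographic sites, each contributing water-column libraries in
three size fractions built from both DNA and RNA templates, plus sediment
libraries (DNA and RNA). Three ecological classes of taxa are simulated:

* ``resident_marine`` — a marine fungal community recurring across samples
  (independent Bernoulli occupancy per library, log-normal read depths);
* ``transient_terrestrial`` — terrestrial spore influx: each taxon appears
  in exactly one DNA-template library with 1-3 reads;
* ``nonfungal_background`` — other eukaryotes, occupying samples like
  residents, so that fungal-fraction statistics are exercisable.

Every emitted read is its source sequence passed through an independent
per-base substitution channel with error rate epsilon (optionally an indel
channel for stress tests), creating the 1-nt satellite variants the d=1
clustering stage is designed to absorb. Full ground truth (read -> source,
source -> class) is returned so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import occfilter
from .iolib import Read, Sample, SampleTable, write_fasta, write_sample_table

__all__ = [
    "TaxonClass",
    "ReferenceRecord",
    "SynthConfig",
    "GroundTruth",
    "generate_reference_db",
    "simulate_dataset",
    "truth_retention_labels",
    "score_against_truth",
    "generate_cellcount_records",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
MIN_REFERENCE_SPACING = 10  # edits; makes OTU identity unambiguous


class TaxonClass(str, Enum):
    RESIDENT_MARINE = "resident_marine"
    TRANSIENT_TERRESTRIAL = "transient_terrestrial"
    NONFUNGAL_BACKGROUND = "nonfungal_background"


@dataclass(frozen=True)
class ReferenceRecord:
    """A taxonomy-labelled reference sequence with provenance annotation."""

    ref_id: str
    sequence: str
    taxonomy_path: tuple[str, ...]
    is_marine: bool
    is_fungal: bool


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and noise parameters for the synthetic community.

    Defaults mirror the emulated survey where it states them (6 sites; 3
    water-column size fractions x {DNA, RNA}; sediment DNA+RNA per site) and
    desk-scale conventions where it does not (per-sample depths).
    """

    n_sites: int = 6
    n_water_fractions: int = 3
    n_sediment_samples: int = 1          # per site, each as DNA + RNA
    n_resident_taxa: int = 20
    n_transient_taxa: int = 200
    n_background_taxa: int = 20          # non-fungal residents
    reads_per_sample: int = 150          # expected total reads per library
    read_length: int = 380               # typical V4 amplicon length
    epsilon: float = 0.002               # per-base substitution rate
    indel_rate: float = 0.0              # optional stress-test channel
    p_occ: float = 0.6                   # resident per-sample occupancy
    lognorm_sigma: float = 1.0           # depth dispersion per occupied taxon
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_water_fractions, self.n_resident_taxa,
               self.n_transient_taxa, self.reads_per_sample,
               self.read_length) < 1:
            raise ValueError("all design counts must be >= 1")
        if not 0.0 <= self.epsilon < 0.05:
            raise ValueError(f"epsilon must be in [0, 0.05), got {self.epsilon}")
        if not 0.0 < self.p_occ <= 1.0:
            raise ValueError(f"p_occ must be in (0, 1], got {self.p_occ}")

    @property
    def size_fractions(self) -> list[str]:
        return ["0.8-20um", "20-2000um", "3-20um"][: self.n_water_fractions]

    def build_sample_table(self) -> SampleTable:
        samples: list[Sample] = []
        for s in range(self.n_sites):
            site = f"Site{s + 1:02d}"
            for f, fraction in enumerate(self.size_fractions):
                for template in ("DNA", "RNA"):
                    samples.append(Sample(
                        sample_id=f"{site}.WC.F{f + 1}.{template}",
                        site=site, substrate="water_column", depth="surface",
                        size_fraction=fraction, template=template,
                    ))
            for k in range(self.n_sediment_samples):
                for template in ("DNA", "RNA"):
                    samples.append(Sample(
                        sample_id=f"{site}.SED{k + 1}.{template}",
                        site=site, substrate="sediment", depth="seafloor",
                        size_fraction="bulk", template=template,
                    ))
        return SampleTable(samples)


@dataclass
class GroundTruth:
    """Truth labels: which reference each read came from, and each
    reference's ecological class."""

    read_to_ref: dict[str, str]
    ref_class: dict[str, TaxonClass]
    # realized occupancy: ref_id -> set of sample_ids with >=1 emitted read
    ref_samples: dict[str, set[str]] = field(default_factory=dict)

    def class_of_read(self, read_id: str) -> TaxonClass:
        return self.ref_class[self.read_to_ref[read_id]]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_reference_db(config: SynthConfig,
                          seed: int | None = None) -> list[ReferenceRecord]:
    """Draw reference sequences with pairwise edit distance >= 10.

    Random sequences at V4 length are essentially always far apart; any
    accidental near-duplicate is redrawn. Resident taxa are marked marine
    fungi; transient taxa are non-marine fungi; background taxa are
    non-fungal (half of them marine, emulating other marine eukaryotes).
    """
    import edlib

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_total = (config.n_resident_taxa + config.n_transient_taxa
               + config.n_background_taxa)
    max_distinct = 4 ** min(config.read_length, 20)
    if n_total > max_distinct:
        raise ValueError(
            f"cannot place {n_total} references >= {MIN_REFERENCE_SPACING} "
            f"edits apart at length {config.read_length}")

    sequences: list[str] = []
    attempts = 0
    while len(sequences) < n_total:
        cand = _random_sequence(rng, config.read_length)
        ok = all(
            edlib.align(cand, s, task="distance",
                        k=MIN_REFERENCE_SPACING - 1)["editDistance"] == -1
            for s in sequences)
        if ok:
            sequences.append(cand)
        attempts += 1
        if attempts > 50 * n_total:
            raise ValueError(
                f"could not satisfy the {MIN_REFERENCE_SPACING}-edit spacing "
                f"for {n_total} references of length {config.read_length}")

    records: list[ReferenceRecord] = []
    idx = iter(sequences)
    dikarya_cycle = ["Ascomycota", "Basidiomycota"]
    chytrid_cycle = ["Chytridiomycota", "Cryptomycota"]
    for i in range(config.n_resident_taxa):
        phylum = (dikarya_cycle + chytrid_cycle)[i % 4]
        records.append(ReferenceRecord(
            ref_id=f"RES{i:03d}", sequence=next(idx),
            taxonomy_path=("Fungi", phylum, f"ResidentGenus{i}"),
            is_marine=True, is_fungal=True))
    for i in range(config.n_transient_taxa):
        phylum = dikarya_cycle[i % 2]
        records.append(ReferenceRecord(
            ref_id=f"TRA{i:03d}", sequence=next(idx),
            taxonomy_path=("Fungi", phylum, f"TerrestrialGenus{i}"),
            is_marine=False, is_fungal=True))
    for i in range(config.n_background_taxa):
        records.append(ReferenceRecord(
            ref_id=f"BKG{i:03d}", sequence=next(idx),
            taxonomy_path=("Eukaryota", "OtherEukaryote", f"BackgroundGenus{i}"),
            is_marine=(i % 2 == 0), is_fungal=False))
    return records


def _mutate(rng: np.random.Generator, sequence: str, epsilon: float,
            indel_rate: float) -> str:
    seq = np.frombuffer(sequence.encode(), dtype="S1").copy()
    if epsilon > 0:
        hits = np.nonzero(rng.random(seq.size) < epsilon)[0]
        for pos in hits:
            alternatives = _BASES[_BASES != seq[pos]]
            seq[pos] = alternatives[rng.integers(0, 3)]
    out = seq.tobytes().decode()
    if indel_rate > 0:
        chars = list(out)
        i = 0
        while i < len(chars):
            r = rng.random()
            if r < indel_rate / 2 and len(chars) > 1:
                del chars[i]
            elif r < indel_rate:
                chars.insert(i, str(_BASES[rng.integers(0, 4)], "ascii"))
                i += 2
            else:
                i += 1
        out = "".join(chars)
    return out


def simulate_dataset(
    refdb: list[ReferenceRecord],
    config: SynthConfig,
    seed: int | None = None,
) -> tuple[list[Read], SampleTable, GroundTruth]:
    """Realize the community design into provenance-tagged reads.

    Residents and background taxa enter each library independently with
    probability ``p_occ``; an occupied taxon's depth is log-normal, scaled so
    a library's expected total is ``reads_per_sample``. Each transient taxon
    is placed in exactly one DNA-template library with 1-3 reads. Every read
    passes through the substitution (and optional indel) channel.
    """
    if not refdb:
        raise ValueError("reference database is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sample_table = config.build_sample_table()
    samples = list(sample_table)
    dna_samples = [s for s in samples if s.template == "DNA"]

    residents = [r for r in refdb if r.ref_id.startswith(("RES", "BKG"))]
    transients = [r for r in refdb if r.ref_id.startswith("TRA")]
    by_id = {r.ref_id: r for r in refdb}

    # per-occupied-taxon depth: LogNormal(mu, sigma) with mu chosen so the
    # expected per-library total matches reads_per_sample
    n_occ_expected = max(len(residents) * config.p_occ, 1e-9)
    mean_depth = config.reads_per_sample / n_occ_expected
    mu = np.log(mean_depth) - config.lognorm_sigma ** 2 / 2

    reads: list[Read] = []
    read_to_ref: dict[str, str] = {}
    ref_samples: dict[str, set[str]] = {r.ref_id: set() for r in refdb}
    counter = 0

    def emit(ref: ReferenceRecord, sample_id: str, n: int) -> None:
        nonlocal counter
        for _ in range(n):
            seq = _mutate(rng, ref.sequence, config.epsilon, config.indel_rate)
            rid = f"r{counter:07d}"
            counter += 1
            reads.append(Read(read_id=rid, sample_id=sample_id, sequence=seq))
            read_to_ref[rid] = ref.ref_id
            ref_samples[ref.ref_id].add(sample_id)

    for sample in samples:
        for ref in residents:
            if rng.random() < config.p_occ:
                depth = max(1, int(round(
                    rng.lognormal(mu, config.lognorm_sigma))))
                emit(ref, sample.sample_id, depth)
    for ref in transients:
        sample = dna_samples[rng.integers(0, len(dna_samples))]
        emit(ref, sample.sample_id, int(rng.integers(1, 4)))

    truth = GroundTruth(
        read_to_ref=read_to_ref,
        ref_class={
            r.ref_id: (
                TaxonClass.RESIDENT_MARINE if r.ref_id.startswith("RES")
                else TaxonClass.TRANSIENT_TERRESTRIAL if r.ref_id.startswith("TRA")
                else TaxonClass.NONFUNGAL_BACKGROUND)
            for r in refdb},
        ref_samples={k: v for k, v in ref_samples.items()},
    )
    assert len(reads) == len(read_to_ref), "read-count conservation violated"
    return reads, sample_table, truth


def truth_retention_labels(
    truth: GroundTruth,
    sample_table: SampleTable,
) -> dict[str, bool]:
    """Expected filter outcome per reference taxon, from TRUE occupancy.

    Applies the multi-occurrence rule to each taxon's realized sample set:
    retain iff occurring in >=2 samples with >=1 RNA library, or >=3 samples.
    """
    labels: dict[str, bool] = {}
    for ref_id, sset in truth.ref_samples.items():
        if not sset:
            continue  # taxon never realized; no expectation
        n_rna = sum(1 for sid in sset if sample_table[sid].template == "RNA")
        profile = occfilter.OccurrenceProfile(
            cluster_id=ref_id, n_samples=len(sset),
            n_rna_samples=n_rna, n_dna_samples=len(sset) - n_rna)
        labels[ref_id] = occfilter.passes_filter(profile)
    return labels


def score_against_truth(
    retained: list,
    truth: GroundTruth,
    sample_table: SampleTable,
) -> dict[str, float]:
    """Recovery scores of a filtered clustering against the ground truth.

    Each cluster is attributed to the majority source taxon of its reads;
    a taxon counts as retained iff one of its clusters passed the filter.
    Returns resident retention recall (over residents the rule should
    retain, per :func:`truth_retention_labels`) and transient exclusion
    specificity (over transient taxa, which the rule should always drop).
    """
    from collections import Counter

    expected = truth_retention_labels(truth, sample_table)

    def source_of(cluster) -> str:
        return Counter(
            truth.read_to_ref[rid] for rid in cluster.read_ids).most_common(1)[0][0]

    retained_refs = {source_of(c) for c in retained}
    resident_expected = [
        r for r, keep in expected.items()
        if keep and truth.ref_class[r] is TaxonClass.RESIDENT_MARINE]
    transients = [
        r for r in expected
        if truth.ref_class[r] is TaxonClass.TRANSIENT_TERRESTRIAL]
    recall = (sum(1 for r in resident_expected if r in retained_refs)
              / len(resident_expected)) if resident_expected else float("nan")
    specificity = (sum(1 for r in transients if r not in retained_refs)
                   / len(transients)) if transients else float("nan")
    return {"resident_retention_recall": recall,
            "transient_exclusion_specificity": specificity,
            "n_resident_expected_retained": len(resident_expected),
            "n_transient_realized": len(transients)}


def generate_cellcount_records(
    n_samples: int = 10,
    seed: int = 42,
    slope: float = 1.0,
    noise_sd: float = 0.4,
) -> pd.DataFrame:
    """Synthetic microscopy analogue of the chitin-wall cell-count survey.

    Ten water-column samples with total eukaryote densities of a few
    thousand cells/ml and chitin-walled fractions in the 0.15-1.75% band;
    the RNA-tag fungal percentage is a noisy affine function of the chitin
    percentage so regression concordance is exercisable with known truth.
    Columns match the cell-count TSV contract of :mod:`marfungi.cellcounts`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        total = float(rng.uniform(2000, 9000))
        pct_chitin = float(rng.uniform(0.15, 1.75))
        mean_chitin = total * pct_chitin / 100.0
        reps = np.maximum(
            rng.normal(mean_chitin, 0.15 * mean_chitin + 1e-9, size=3), 0.0)
        pct_rna = max(0.01, slope * pct_chitin + rng.normal(0.0, noise_sd))
        rows.append({
            "sample_id": f"CC{i + 1:02d}",
            "chitin_replicates": ";".join(f"{v:.2f}" for v in reps),
            "total_eukaryote_density": round(total, 1),
            "pct_rna_fungal_reads": round(pct_rna, 4),
        })
    return pd.DataFrame(rows)


def write_dataset(
    outdir: str | Path,
    refdb: list[ReferenceRecord],
    reads: list[Read],
    sample_table: SampleTable,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the synthetic dataset as plain-text artifacts (FASTA + TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fasta",
        "refs": outdir / "references.fasta",
        "ref_meta": outdir / "references.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_fasta([(f"{r.read_id} sample={r.sample_id}", r.sequence)
                 for r in reads], paths["reads"])
    write_fasta([(r.ref_id, r.sequence) for r in refdb], paths["refs"])
    pd.DataFrame(
        [{"ref_id": r.ref_id, "taxonomy": ";".join(r.taxonomy_path),
          "is_marine": int(r.is_marine), "is_fungal": int(r.is_fungal)}
         for r in refdb]).to_csv(paths["ref_meta"], sep="\t", index=False)
    write_sample_table(sample_table, paths["samples"])
    pd.DataFrame(
        [{"read_id": rid, "ref_id": ref,
          "taxon_class": truth.ref_class[ref].value}
         for rid, ref in truth.read_to_ref.items()]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
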