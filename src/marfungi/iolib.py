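"""Readers and writers for every external format the pipeline touches.

All tabular formats are TSV (UTF-8): sample labels routinely contain commas
and micron signs, so CSV is avoided throughout. Sequence data travel as plain
FASTA; dereplicated FASTA uses the de-facto ``;size=N`` abundance dialect.
Every other module consumes and produces the types defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Read",
    "Sample",
    "SampleTable",
    "OtuTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "parse_size_annotation",
    "format_size_annotation",
    "read_sample_table",
    "write_sample_table",
    "read_otu_table",
    "write_otu_table",
]

SUBSTRATES = ("water_column", "sediment")
TEMPLATES = ("DNA", "RNA")

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class Read:
    """A cleaned amplicon read tagged with its library of origin."""

    read_id: str
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"read {self.read_id!r}: ambiguity codes or invalid symbols "
                f"{sorted(bad)} are rejected; reads must be cleaned A/C/G/T"
            )


@dataclass(frozen=True)
class Sample:
    """One nucleic-acid library: site x substrate x depth x fraction x template.

    The DNA and RNA libraries built from the same water sample are two distinct
    samples; this is what lets the RNA clause of the occurrence filter bind.
    """

    sample_id: str
    site: str
    substrate: str
    depth: str
    size_fraction: str
    template: str

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown substrate {self.substrate!r} "
                f"(expected one of {SUBSTRATES})"
            )
        if self.template not in TEMPLATES:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown template {self.template!r} "
                f"(expected one of {TEMPLATES})"
            )


class SampleTable:
    """Ordered collection of samples, unique by sample_id."""

    def __init__(self, samples: Iterable[Sample]):
        self._samples: list[Sample] = list(samples)
        if not self._samples:
            raise FormatError("sample table must contain at least one sample")
        self._by_id: dict[str, Sample] = {}
        for s in self._samples:
            if s.sample_id in self._by_id:
                raise FormatError(f"duplicate sample_id {s.sample_id!r}")
            self._by_id[s.sample_id] = s

    def __iter__(self) -> Iterator[Sample]:
        return iter(self._samples)

    def __len__(self) -> int:
        return len(self._samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> Sample:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self._samples]

    def template_of(self, sample_id: str) -> str:
        return self[sample_id].template


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (id, sequence) pairs in file order.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``. The id is the
    full header line after ``>`` up to the first whitespace.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        if header is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        if not seq:
            raise FormatError(
                f"{path}:{header_line}: record {header!r} has an empty sequence"
            )
        records.append((header, seq))

    with path.open(encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}:{line_no}: empty FASTA header")
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{line_no}: sequence data before any '>' header"
                    )
                chunks.append(line)
        flush(line_no=-1)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# ;size= abundance dialect
# ---------------------------------------------------------------------------

_SIZE_RE = re.compile(r"^(?P<bare>.*?);size=(?P<size>[^;]*);?$")


def parse_size_annotation(fasta_id: str) -> tuple[str, int]:
    """Split ``amp1;size=42`` into (``amp1``, 42); abundance defaults to 1."""
    m = _SIZE_RE.match(fasta_id)
    if m is None:
        return fasta_id, 1
    raw = m.group("size")
    try:
        size = int(raw)
    except ValueError:
        raise FormatError(f"id {fasta_id!r}: size annotation {raw!r} is not an integer")
    if size < 1:
        raise FormatError(f"id {fasta_id!r}: size must be a positive integer, got {size}")
    return m.group("bare"), size


def format_size_annotation(bare_id: str, abundance: int) -> str:
    if abundance < 1:
        raise FormatError(f"abundance must be positive, got {abundance}")
    return f"{bare_id};size={abundance}"


# ---------------------------------------------------------------------------
# Sample table TSV
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = ["sample_id", "site", "substrate", "depth", "size_fraction",
                   "template"]


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a sample-metadata TSV; substrate/template enums are validated
    case-insensitively and normalized."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    samples = []
    for idx, row in df.iterrows():
        substrate = row["substrate"].strip().lower()
        template = row["template"].strip().upper()
        try:
            samples.append(Sample(
                sample_id=row["sample_id"].strip(),
                site=row["site"].strip(),
                substrate=substrate,
                depth=row["depth"].strip(),
                size_fraction=row["size_fraction"].strip(),
                template=template,
            ))
        except FormatError as exc:
            raise FormatError(f"{path}: row {idx + 2}: {exc}") from None
    return SampleTable(samples)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [[s.sample_id, s.site, s.substrate, s.depth, s.size_fraction, s.template]
         for s in table],
        columns=_SAMPLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OTU table TSV
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Read counts: rows = OTU-cluster ids, columns = sample ids."""

    counts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(dtype=int))

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.values < 0).any():
            raise FormatError("OTU table contains negative counts")

    @property
    def cluster_ids(self) -> list[str]:
        return [str(i) for i in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    def cluster_total(self, cluster_id: str) -> int:
        return int(self.counts.loc[cluster_id].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "cluster_id"
    df.to_csv(path, sep="\t")


def read_otu_table(path: str | Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.size and (df.values < 0).any():
        bad = df[(df < 0).any(axis=1)].index.tolist()
        raise FormatError(f"{path}: negative counts in rows {bad}")
    df.index.name = None
    return OtuTable(df.astype(int) if df.size else df)
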