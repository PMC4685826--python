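"""Best-hit taxonomic assignment and the marine-identity flag.

Percent identity is computed on an optimal semi-global alignment: match +1,
mismatch -1, internal gap -2, terminal gap -1 per base on either sequence.
Identity is 100 x matches / aligned columns, where the column count excludes
terminal gaps but counts internal gaps, so a perfect fragment of a longer
reference scores 100. Terminal gaps carry a reduced (not zero) cost: with
fully free end gaps the optimal alignment of two unrelated sequences
degenerates to a few-column perfect terminal overlap, which would report
near-100 identity for arbitrary pairs and make identity thresholds
meaningless. The half-cost keeps fragment matches exact (every alignment of
a fragment/reference pair carries the same end-gap total) while forcing
unrelated pairs to align end to end at their true ~50-65% identity.

A cluster is flagged as matching a marine lineage when its representative is
*strictly* more than 99% identical to some reference annotated as sampled
from a marine environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

from Bio import Align

__all__ = [
    "Assignment",
    "MarineFlag",
    "Lineage",
    "global_identity",
    "assign_taxonomy",
    "flag_marine",
    "partition_by_lineage",
]

DEFAULT_MIN_IDENTITY = 80.0
MARINE_IDENTITY_THRESHOLD = 99.0


@dataclass(frozen=True)
class Assignment:
    cluster_id: str
    best_ref_id: str | None
    percent_identity: float
    taxonomy_path: tuple[str, ...]
    assigned: bool


@dataclass(frozen=True)
class MarineFlag:
    cluster_id: str
    flagged: bool
    best_marine_identity: float


class Lineage(str, Enum):
    DIKARYA = "dikarya"
    CHYTRID_LIKE = "chytrid_like"
    UNASSIGNED = "unassigned"


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # terminal gaps at half cost (see module docstring)
    aligner.open_end_gap_score = -1
    aligner.extend_end_gap_score = -1
    return aligner


def global_identity(query: str, reference: str) -> float:
    """Percent identity of the optimal end-gap-free pairwise alignment."""
    if not query or not reference:
        raise ValueError("global_identity requires non-empty sequences")
    if query == reference:
        return 100.0
    aligner = _aligner()
    if len(query) == len(reference):
        # If the gapless alignment attains the optimal score it is itself an
        # optimal alignment, so identity follows from the mismatch count.
        mismatches = sum(1 for a, b in zip(query, reference) if a != b)
        if aligner.score(query, reference) == len(query) - 2 * mismatches:
            return 100.0 * (len(query) - mismatches) / len(query)
    alignment = next(iter(aligner.align(query, reference)))
    row_q, row_r = str(alignment[0]), str(alignment[1])
    # trim terminal-gap columns (at each end only one row can hold gaps)
    start, end = 0, len(row_q)
    while start < end and (row_q[start] == "-" or row_r[start] == "-"):
        start += 1
    while end > start and (row_q[end - 1] == "-" or row_r[end - 1] == "-"):
        end -= 1
    columns = end - start
    if columns == 0:
        return 0.0
    matches = sum(1 for i in range(start, end) if row_q[i] == row_r[i])
    return 100.0 * matches / columns


def _screen(representative: str, records: list, n_candidates: int | None,
            margin: int = 20) -> list:
    """Candidate screening before exact identity computation.

    Exhaustive semi-global alignment against every reference is wasteful
    when almost all references are unrelated, so — like the k-mer/word
    screening of amplicon search tools — candidates are ranked by global
    edit distance (a cheap proxy) and only those within ``margin`` edits of
    the closest, capped at ``n_candidates``, are aligned exactly.
    ``n_candidates=None`` disables screening (fully exhaustive search).
    """
    if n_candidates is None or len(records) <= (n_candidates or 0):
        return sorted(records, key=lambda r: r.ref_id)
    import edlib

    ranked = sorted(
        ((edlib.align(representative, rec.sequence,
                      task="distance")["editDistance"], rec.ref_id, rec)
         for rec in records),
        key=lambda t: (t[0], t[1]))
    dmin = ranked[0][0]
    return [rec for dist, _, rec in ranked[:n_candidates]
            if dist <= dmin + margin]


def assign_taxonomy(
    cluster_id: str,
    representative: str,
    refdb: list,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    n_candidates: int | None = 8,
) -> Assignment:
    """Best-hit assignment of a cluster representative against the reference
    collection; ties in identity are broken by reference id (ascending).

    ``refdb`` entries need ``ref_id``, ``sequence`` and ``taxonomy_path``
    attributes (see :class:`marfungi.synthdata.ReferenceRecord`). With the
    default candidate screening the hit maximizes identity among the
    ``n_candidates`` references closest in edit distance; pass
    ``n_candidates=None`` for the exhaustive search.
    """
    if not refdb:
        raise ValueError("reference database is empty")
    best_id: str | None = None
    best_pct = -1.0
    best_tax: tuple[str, ...] = ()
    for rec in _screen(representative, refdb, n_candidates):
        pct = global_identity(representative, rec.sequence)
        if pct > best_pct:
            best_id, best_pct, best_tax = rec.ref_id, pct, tuple(rec.taxonomy_path)
    assigned = best_pct >= min_identity
    return Assignment(
        cluster_id=cluster_id,
        best_ref_id=best_id,
        percent_identity=best_pct,
        taxonomy_path=best_tax if assigned else (),
        assigned=assigned,
    )


def flag_marine(cluster_id: str, representative: str, refdb: list,
                n_candidates: int | None = 8) -> MarineFlag:
    """Highest identity to any marine-annotated reference; flag iff > 99%."""
    marine = [rec for rec in refdb if getattr(rec, "is_marine", False)]
    best = 0.0
    for rec in _screen(representative, marine, n_candidates) if marine else []:
        pct = global_identity(representative, rec.sequence)
        if pct > best:
            best = pct
    return MarineFlag(
        cluster_id=cluster_id,
        flagged=best > MARINE_IDENTITY_THRESHOLD,
        best_marine_identity=best,
    )


_DIKARYA_LABELS = {"ascomycota", "basidiomycota", "dikarya"}
_CHYTRID_LABELS = {
    "chytridiomycota", "cryptomycota", "rozellomycota", "rozellida",
    "aphelida", "aphelidea", "cra",
}


def partition_by_lineage(assignments: list[Assignment]) -> dict[str, Lineage]:
    """Bucket clusters into Dikarya vs chytrid-like vs unassigned by the
    top-level labels of their best-hit taxonomy path."""
    out: dict[str, Lineage] = {}
    for a in assignments:
        labels = {label.strip().lower() for label in a.taxonomy_path}
        if not a.assigned:
            out[a.cluster_id] = Lineage.UNASSIGNED
        elif labels & _DIKARYA_LABELS:
            out[a.cluster_id] = Lineage.DIKARYA
        elif labels & _CHYTRID_LABELS:
            out[a.cluster_id] = Lineage.CHYTRID_LIKE
        else:
            out[a.cluster_id] = Lineage.UNASSIGNED
    return out
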