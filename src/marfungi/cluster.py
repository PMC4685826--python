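"""Dereplication and the two-stage OTU clustering hierarchy.

Stage one is single-linkage amplicon clustering at a small edit-distance
radius ``d`` (default 1): amplicons are seeds in decreasing abundance order
and an OTU is the transitive closure of the <=d Levenshtein-neighbour graph,
so two amplicons share an OTU iff a chain of <=d steps connects them. Stage
two greedily re-clusters OTU representatives: each representative, again in
decreasing abundance order, joins the first cluster whose *founder* is within
``max_diff`` edits (greedy centroid semantics), else founds a new cluster.

For d=1 the neighbour search uses a symmetric-deletion index (every sequence
keys itself and each of its single-character deletions; two sequences within
one edit necessarily share a key), which reduces candidate generation from
quadratic to near-linear; candidates are verified with a banded edit-distance
computation. For d != 1 a length-bucketed pairwise scan is used. The contract
is the partition, not the algorithm.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib

from .iolib import Read

__all__ = [
    "Amplicon",
    "Otu",
    "OtuCluster",
    "dereplicate",
    "edit_distance",
    "swarm_cluster",
    "recluster_representatives",
]


@dataclass
class Amplicon:
    """A distinct sequence with the reads that carry it."""

    sequence: str
    read_ids: list[str]

    @property
    def abundance(self) -> int:
        return len(self.read_ids)


@dataclass
class Otu:
    """Single-linkage cluster of amplicons; representative = most abundant."""

    members: list[Amplicon]

    @property
    def representative(self) -> Amplicon:
        return self.members[0]

    @property
    def total_reads(self) -> int:
        return sum(a.abundance for a in self.members)

    @property
    def read_ids(self) -> list[str]:
        return [rid for a in self.members for rid in a.read_ids]


@dataclass
class OtuCluster:
    """Second-level cluster of OTUs, with per-sample read counts."""

    cluster_id: str
    members: list[Otu]
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def representative_sequence(self) -> str:
        return self.members[0].representative.sequence

    @property
    def total_reads(self) -> int:
        return sum(o.total_reads for o in self.members)

    @property
    def read_ids(self) -> list[str]:
        return [rid for o in self.members for rid in o.read_ids]


def dereplicate(reads: list[Read]) -> list[Amplicon]:
    """Collapse identical sequences into amplicons.

    Output is sorted by (abundance desc, sequence asc) — the canonical order
    both clustering stages rely on for determinism. Empty input yields an
    empty list.
    """
    by_seq: dict[str, list[str]] = defaultdict(list)
    for read in reads:
        by_seq[read.sequence].append(read.read_id)
    amplicons = [Amplicon(seq, rids) for seq, rids in by_seq.items()]
    amplicons.sort(key=lambda a: (-a.abundance, a.sequence))
    return amplicons


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions, deletions)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def _within(a: str, b: str, d: int) -> bool:
    if abs(len(a) - len(b)) > d:
        return False
    return edlib.align(a, b, task="distance", k=d)["editDistance"] != -1


def _deletion_keys(seq: str) -> set[int]:
    # The sequence itself plus every single-deletion variant, hashed.
    keys = {hash(seq)}
    for i in range(len(seq)):
        keys.add(hash(seq[:i] + seq[i + 1:]))
    return keys


def _neighbour_lists_d1(seqs: list[str]) -> list[list[int]]:
    """Adjacency lists of the Levenshtein-distance-<=1 graph via symmetric
    deletion: candidates share a deletion key, then are verified exactly."""
    index: dict[int, list[int]] = defaultdict(list)
    keysets = []
    for i, s in enumerate(seqs):
        ks = _deletion_keys(s)
        keysets.append(ks)
        for k in ks:
            index[k].append(i)
    adj: list[list[int]] = [[] for _ in seqs]
    for i, ks in enumerate(keysets):
        cand = set()
        for k in ks:
            cand.update(index[k])
        cand.discard(i)
        for j in cand:
            if j > i and _within(seqs[i], seqs[j], 1):
                adj[i].append(j)
                adj[j].append(i)
    return adj


def _neighbour_lists_generic(seqs: list[str], d: int) -> list[list[int]]:
    order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
    adj: list[list[int]] = [[] for _ in seqs]
    for a in range(len(order)):
        i = order[a]
        for b in range(a + 1, len(order)):
            j = order[b]
            if len(seqs[j]) - len(seqs[i]) > d:
                break
            if _within(seqs[i], seqs[j], d):
                adj[i].append(j)
                adj[j].append(i)
    return adj


def swarm_cluster(amplicons: list[Amplicon], d: int = 1) -> list[Otu]:
    """Partition amplicons into OTUs by single-linkage at radius ``d``.

    OTUs are emitted in order of decreasing seed abundance (ties broken by
    sequence); within an OTU members are sorted the same way, so the first
    member is the representative. The partition is invariant to input order.
    """
    if d < 0:
        raise ValueError(f"clustering radius d must be >= 0, got {d}")
    if not amplicons:
        return []
    pool = sorted(amplicons, key=lambda a: (-a.abundance, a.sequence))
    seqs = [a.sequence for a in pool]
    if len(set(seqs)) != len(seqs):
        raise ValueError("amplicons must be dereplicated (duplicate sequences found)")
    if d == 0:
        return [Otu([a]) for a in pool]
    adj = _neighbour_lists_d1(seqs) if d == 1 else _neighbour_lists_generic(seqs, d)

    assigned = [False] * len(pool)
    otus: list[Otu] = []
    for seed in range(len(pool)):
        if assigned[seed]:
            continue
        # breadth-first growth over the <=d neighbour graph
        component = [seed]
        assigned[seed] = True
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if not assigned[v]:
                        assigned[v] = True
                        component.append(v)
                        nxt.append(v)
            frontier = nxt
        members = sorted((pool[i] for i in component),
                         key=lambda a: (-a.abundance, a.sequence))
        otus.append(Otu(members))
    return otus


def recluster_representatives(
    otus: list[Otu],
    read_samples: dict[str, str],
    max_diff: int = 1,
) -> list[OtuCluster]:
    """Greedily merge OTUs whose representatives are within ``max_diff`` edits.

    Representatives are processed in (abundance desc, sequence asc) order of
    their OTU's total reads; each joins the first existing cluster whose
    FOUNDER representative is within ``max_diff``, else founds a new cluster.
    Comparing against founders only (not all members) keeps the stage
    deterministic and mirrors greedy centroid clustering tools.

    ``read_samples`` maps read_id -> sample_id and is used to aggregate the
    per-sample read counts of each cluster.
    """
    if max_diff < 0:
        raise ValueError(f"max_diff must be >= 0, got {max_diff}")
    ordered = sorted(
        otus, key=lambda o: (-o.total_reads, o.representative.sequence))
    founders: list[str] = []
    clusters: list[list[Otu]] = []
    for otu in ordered:
        rep = otu.representative.sequence
        for ci, founder_seq in enumerate(founders):
            if _within(rep, founder_seq, max_diff):
                clusters[ci].append(otu)
                break
        else:
            founders.append(rep)
            clusters.append([otu])

    result: list[OtuCluster] = []
    for ci, members in enumerate(clusters):
        counts: dict[str, int] = defaultdict(int)
        for otu in members:
            for rid in otu.read_ids:
                try:
                    counts[read_samples[rid]] += 1
                except KeyError:
                    raise KeyError(f"read {rid!r} has no sample assignment") from None
        result.append(OtuCluster(
            cluster_id=f"C{ci:04d}",
            members=members,
            sample_counts=dict(counts),
        ))
    return result
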