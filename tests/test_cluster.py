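import pytest

from marfungi.cluster import (Amplicon, dereplicate, edit_distance,
                              recluster_representatives, swarm_cluster)
from marfungi.iolib import Read

from .conftest import dp_levenshtein, mutate_subs, random_seq


def brute_force_partition(seqs: list[str], d: int) -> set[frozenset[str]]:
    """Connected components of the <=d edit-distance graph (union-find)."""
    parent = list(range(len(seqs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if dp_levenshtein(seqs[i], seqs[j]) <= d:
                parent[find(i)] = find(j)
    comps = {}
    for i, s in enumerate(seqs):
        comps.setdefault(find(i), set()).add(s)
    return {frozenset(c) for c in comps.values()}


def reads_from(seqs: list[str]) -> list[Read]:
    return [Read(f"r{i}", "S1", s) for i, s in enumerate(seqs)]


class TestDereplicate:
    def test_collapses_identical_sequences(self):
        amps = dereplicate(reads_from(["ACGT", "ACGT", "ACGT", "TTTT"]))
        assert [(a.sequence, a.abundance) for a in amps] == \
            [("ACGT", 3), ("TTTT", 1)]

    def test_all_distinct(self):
        amps = dereplicate(reads_from(["AAAA", "CCCC", "GGGG"]))
        assert all(a.abundance == 1 for a in amps)

    def test_abundance_conservation(self, rng):
        seqs = [random_seq(rng, 8) for _ in range(1000)]
        amps = dereplicate(reads_from(seqs))
        assert sum(a.abundance for a in amps) == 1000

    def test_empty_input(self):
        assert dereplicate([]) == []


class TestEditDistance:
    @pytest.mark.parametrize("a,b,d", [
        ("ACGT", "ACGT", 0), ("ACGT", "AGGT", 1), ("ACGT", "ACGTT", 1),
        ("", "ACG", 3),
    ])
    def test_known_values(self, a, b, d):
        assert edit_distance(a, b) == d

    def test_agrees_with_dp_oracle(self, rng):
        for _ in range(200):
            a = random_seq(rng, int(rng.integers(1, 30)))
            b = random_seq(rng, int(rng.integers(1, 30)))
            assert edit_distance(a, b) == dp_levenshtein(a, b)
            assert edit_distance(a, b) == edit_distance(b, a)


class TestSwarmCluster:
    def test_chain_links_through_intermediate(self):
        # A-B and B-C at distance 1, A-C at distance 2: one OTU
        a, b, c = "AAAAAAAA", "AAAAAAAT", "AAAAAATT"
        amps = [Amplicon(a, ["r"] * 10), Amplicon(b, ["r"] * 3),
                Amplicon(c, ["r"])]
        otus = swarm_cluster(amps, d=1)
        assert len(otus) == 1
        assert otus[0].representative.sequence == a

    def test_distant_amplicons_stay_separate(self):
        amps = [Amplicon("AAAAAAAA", ["r"]), Amplicon("AATTTAAA", ["r"])]
        assert len(swarm_cluster(amps, d=1)) == 2

    def test_singleton(self):
        otus = swarm_cluster([Amplicon("ACGT", ["r1"])])
        assert len(otus) == 1
        assert otus[0].representative.sequence == "ACGT"

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            swarm_cluster([Amplicon("ACGT", ["r"])], d=-1)

    def test_duplicate_sequences_rejected(self):
        with pytest.raises(ValueError, match="dereplicated"):
            swarm_cluster([Amplicon("ACGT", ["a"]), Amplicon("ACGT", ["b"])])

    @pytest.mark.parametrize("d", [1, 2])
    def test_matches_brute_force_components(self, rng, d):
        """Random instances: partition equals connected components of the
        <=d-distance graph computed by an independent DP + union-find."""
        for _ in range(40):
            n = int(rng.integers(2, 30))
            base = random_seq(rng, int(rng.integers(5, 20)))
            seqs = {base}
            while len(seqs) < n:
                src = list(seqs)[int(rng.integers(0, len(seqs)))]
                seqs.add(mutate_subs(rng, src,
                                     min(int(rng.integers(1, 4)), len(src))))
            seqs = sorted(seqs)
            amps = [Amplicon(s, [f"r{i}"] * int(rng.integers(1, 5)))
                    for i, s in enumerate(seqs)]
            got = {frozenset(a.sequence for a in o.members)
                   for o in swarm_cluster(amps, d=d)}
            assert got == brute_force_partition(seqs, d)

    def test_permutation_invariance(self, rng):
        seqs = list({random_seq(rng, 10) for _ in range(20)})
        amps = [Amplicon(s, [f"r{i}"]) for i, s in enumerate(seqs)]
        ref = [frozenset(a.sequence for a in o.members)
               for o in swarm_cluster(amps, d=1)]
        for _ in range(5):
            perm = list(rng.permutation(len(amps)))
            got = [frozenset(a.sequence for a in o.members)
                   for o in swarm_cluster([amps[i] for i in perm], d=1)]
            assert got == ref

    def test_read_conservation(self, rng):
        seqs = [random_seq(rng, 12) for _ in range(300)]
        reads = reads_from(seqs)
        otus = swarm_cluster(dereplicate(reads), d=1)
        assert sum(o.total_reads for o in otus) == len(reads)


class TestRecluster:
    def _otus(self, seqs_with_counts):
        return [
            swarm_cluster([Amplicon(s, [f"{s}_{i}" for i in range(k)])])[0]
            for s, k in seqs_with_counts]

    def test_distance_one_merges(self):
        otus = self._otus([("AAAAAAAA", 5), ("AAAAAAAT", 2)])
        rs = {rid: "S1" for o in otus for rid in o.read_ids}
        clusters = recluster_representatives(otus, rs, max_diff=1)
        assert len(clusters) == 1
        assert clusters[0].total_reads == 7
        assert clusters[0].sample_counts == {"S1": 7}

    def test_distance_two_stays_separate(self):
        otus = self._otus([("AAAAAAAA", 5), ("AAAAAATT", 2)])
        assert dp_levenshtein("AAAAAAAA", "AAAAAATT") == 2
        rs = {rid: "S1" for o in otus for rid in o.read_ids}
        assert len(recluster_representatives(otus, rs, max_diff=1)) == 2

    def test_founder_semantics(self):
        # B joins founder A (d=1); C is d=1 from B but d=2 from founder A,
        # so C founds its own cluster (greedy centroid behaviour).
        otus = self._otus([("AAAAAAAA", 5), ("AAAAAAAT", 3), ("AAAAAATT", 2)])
        rs = {rid: "S1" for o in otus for rid in o.read_ids}
        clusters = recluster_representatives(otus, rs, max_diff=1)
        assert len(clusters) == 2
        assert clusters[0].total_reads == 8
        assert clusters[1].total_reads == 2

    def test_deterministic(self, rng):
        seqs = list({random_seq(rng, 10) for _ in range(15)})
        otus = self._otus([(s, int(rng.integers(1, 6))) for s in seqs])
        rs = {rid: "S1" for o in otus for rid in o.read_ids}
        first = [c.representative_sequence
                 for c in recluster_representatives(otus, rs)]
        second = [c.representative_sequence
                  for c in recluster_representatives(otus[::-1], rs)]
        assert first == second

    def test_negative_max_diff_rejected(self):
        with pytest.raises(ValueError):
            recluster_representatives([], {}, max_diff=-1)


class TestNoiseAbsorption:
    def test_one_edit_reads_join_source_otu(self, rng):
        """Reads one substitution away from an abundant source sequence end
        up in the source's OTU."""
        source = random_seq(rng, 60)
        reads = [Read(f"src{i}", "S1", source) for i in range(20)]
        sats = [mutate_subs(rng, source, 1) for _ in range(10)]
        reads += [Read(f"sat{i}", "S1", s) for i, s in enumerate(sats)]
        otus = swarm_cluster(dereplicate(reads), d=1)
        assert len(otus) == 1
        assert otus[0].representative.sequence == source
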