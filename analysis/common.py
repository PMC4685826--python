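"""Shared study configuration for the numbered analysis scripts.

Every script regenerates what it needs deterministically from this one
config, so the steps can be run independently and in any order. Bulky
intermediates (the read FASTA) go under scratch/; summary tables go under
results/analysis/.
"""

from pathlib import Path

from marfungi import synthdata
from marfungi.cluster import dereplicate, recluster_representatives, swarm_cluster

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results" / "analysis"
SCRATCH = REPO / "scratch" / "analysis"

STUDY = synthdata.SynthConfig()  # 6 sites, 20 resident / 200 transient, eps=0.002


def get_dataset():
    refdb = synthdata.generate_reference_db(STUDY)
    reads, samples, truth = synthdata.simulate_dataset(refdb, STUDY)
    return refdb, reads, samples, truth


def get_clusters(reads):
    otus = swarm_cluster(dereplicate(reads), d=1)
    clusters = recluster_representatives(
        otus, {r.read_id: r.sample_id for r in reads}, max_diff=1)
    return otus, clusters
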