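"""Biogeography of the retained OTU clusters.

Builds the site-level provenance matrix, lists clusters recovered from three
or more geographical sites, computes the fungal fraction of sequencing
effort per substrate, and summarizes within-cluster read similarity. Writes
the matrix to results/analysis/04_provenance_site.tsv and the summary to
results/analysis/04_biogeo.json.
"""

import json

from common import RESULTS, get_clusters, get_dataset
from marfungi import biogeo, occfilter, taxonomy


def main():
    refdb, reads, samples, truth = get_dataset()
    _, clusters = get_clusters(reads)
    assignments = [
        taxonomy.assign_taxonomy(c.cluster_id, c.representative_sequence, refdb)
        for c in clusters]
    fungal_ids = {a.cluster_id for a in assignments
                  if a.assigned and a.taxonomy_path[0] == "Fungi"}
    retained, _, _ = occfilter.apply_filter(
        [c for c in clusters if c.cluster_id in fungal_ids], samples)

    matrix = biogeo.provenance_matrix(retained, samples, ["site"])
    multi = biogeo.multi_site_clusters(matrix, min_sites=3)

    totals, fungal_by_sub = {}, {}
    for r in reads:
        sub = samples[r.sample_id].substrate
        totals[sub] = totals.get(sub, 0) + 1
    for c in retained:
        for sid, n in c.sample_counts.items():
            sub = samples[sid].substrate
            fungal_by_sub[sub] = fungal_by_sub.get(sub, 0) + n
    fractions = biogeo.substrate_fungal_fraction(fungal_by_sub, totals)

    sim = biogeo.within_cluster_similarity(
        retained, {r.read_id: r.sequence for r in reads})

    RESULTS.mkdir(parents=True, exist_ok=True)
    matrix.rename_axis("cluster_id").to_csv(
        RESULTS / "04_provenance_site.tsv", sep="\t")
    (RESULTS / "04_biogeo.json").write_text(json.dumps({
        "multi_site_clusters": multi,
        "substrate_fungal_pct": {k: round(v, 3) for k, v in fractions.items()},
        "within_cluster_similarity": {
            "grand_mean": round(sim.grand_mean, 3),
            "sem": round(sim.sem, 4),
            "minimum": round(sim.minimum, 3),
            "n_singletons": len(sim.singleton_clusters)},
    }, indent=2) + "\n")

    print(f"{len(multi)}/{len(retained)} retained clusters occur at >=3 of "
          f"{matrix.shape[1]} sites — the repeat-sampled resident community")
    print("fungal % of sequencing effort per substrate: "
          + ", ".join(f"{k}={v:.2f}%" for k, v in sorted(fractions.items())))
    print(f"within-cluster similarity: mean {sim.grand_mean:.2f}% "
          f"(s.e.m. {sim.sem:.3f}), minimum {sim.minimum:.2f}% — the d=1 "
          f"clustering keeps clusters far tighter than the reference spacing")


if __name__ == "__main__":
    main()
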