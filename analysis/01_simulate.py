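"""Generate the synthetic multi-site amplicon survey and report its shape.

Writes the full dataset (reads, references, sample table, ground truth) to
scratch/analysis/dataset and a per-sample read-count summary to
results/analysis/01_sample_depths.tsv.
"""

import pandas as pd

from common import RESULTS, SCRATCH, STUDY, get_dataset
from marfungi import synthdata


def main():
    refdb, reads, samples, truth = get_dataset()
    outdir = SCRATCH / "dataset"
    paths = synthdata.write_dataset(outdir, refdb, reads, samples, truth)

    depths = pd.Series([r.sample_id for r in reads]).value_counts()
    RESULTS.mkdir(parents=True, exist_ok=True)
    depths.rename_axis("sample_id").rename("n_reads").sort_index().to_csv(
        RESULTS / "01_sample_depths.tsv", sep="\t")

    n_classes = pd.Series(
        [truth.ref_class[ref].value for ref in truth.read_to_ref.values()]
    ).value_counts()
    print(f"simulated {len(reads)} reads across {len(samples)} samples "
          f"({STUDY.n_sites} sites), {len(refdb)} reference taxa")
    print("reads per taxon class:")
    print(n_classes.to_string())
    print(f"dataset written to {outdir}")
    for name, p in paths.items():
        print(f"  {name}: {p.name}")


if __name__ == "__main__":
    main()
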