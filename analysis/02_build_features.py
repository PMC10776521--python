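#!/usr/bin/env python
"""Build the two modality feature tables.

Structural: the 221-feature morphometric schema per subject.  Functional:
pairwise Pearson correlations between regional timeseries, Fisher
z-transformed and scaled by sqrt(T-3), vectorized over the upper triangle
(R(R-1)/2 features after cohort-wide region filtering).  Writes the combined
table to results/run/features.tsv.
"""

from neurofuse import pipeline

CFG = pipeline.RunConfig(seed=1, out_dir="results/run")


def main() -> None:
    table = pipeline.stage_features(CFG)
    counts = table.modality.value_counts()
    print(f"feature table: {table.df.shape[0]} subjects x {table.df.shape[1]} features")
    print(f"  structural {counts.get('structural', 0)}, "
          f"functional {counts.get('functional', 0)}")
    removed = table.provenance.get("removed_regions", {})
    print(f"  regions removed by missingness filter: {len(removed)}")


if __name__ == "__main__":
    main()
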