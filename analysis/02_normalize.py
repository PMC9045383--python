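#!/usr/bin/env python
"""Reference-community normalization of each subject's OTU time series.

Fractional abundances are compositional: one blooming taxon deflates all
others. Each time point is rescaled toward a reference built from the
other, most similar time points (JSD-weighted medians, weights (1-j)^2),
which stabilizes the non-blooming taxa. Outputs one normalized table and
one scale-factor sidecar per subject.
"""

from pathlib import Path

from microdyn.io import read_otu_table
from microdyn.refnorm import normalize_subject

COHORT = Path("results/cohort")
OUT = Path("results/normalized")
OUT.mkdir(parents=True, exist_ok=True)

table = read_otu_table(COHORT / "otu_table.tsv", COHORT / "metadata.tsv")
for subject in sorted(table.metadata["subject"].unique()):
    series = normalize_subject(table, subject, threshold=0.90)
    series.abundances.to_csv(OUT / f"norm_{subject}.tsv", sep="\t")
    series.scale_factors.to_frame().to_csv(
        OUT / f"scale_factors_{subject}.tsv", sep="\t"
    )
    sf = series.scale_factors
    print(
        f"subject {subject}: {len(series.abundant_otus)} abundant OTUs "
        f"(90% of median reads); scale factors "
        f"{sf.min():.3f}-{sf.max():.3f} (median {sf.median():.3f})"
    )
print(f"wrote normalized series under {OUT}/")
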