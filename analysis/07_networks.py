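#!/usr/bin/env python
"""Genus-cytokine co-occurrence networks inside the enclosure.

For each subject's inside-phase samples: genera with mean relative
abundance above 1% are rank-correlated with each other and with the
cytokine panel; edges require |rho| >= 0.5, significance uses raw
p <= 0.05 with BH q-values reported alongside. The cohort plants three
genus-cytokine links (TNF-a ~ G01 +, IL-10 ~ G03 -, IL-1b ~ G05 +),
which should reappear as edges when the genera pass the filter.
"""

from pathlib import Path

from microdyn.io import read_cytokines, read_otu_table, read_taxonomy
from microdyn.network import build_network

COHORT = Path("results/cohort")
OUT = Path("results/networks")
OUT.mkdir(parents=True, exist_ok=True)

table = read_otu_table(COHORT / "otu_table.tsv", COHORT / "metadata.tsv")
taxonomy = read_taxonomy(COHORT / "taxonomy.tsv")
cytokines = read_cytokines(COHORT / "cytokines.tsv")

for subject in sorted(table.metadata["subject"].unique()):
    net = build_network(table, taxonomy, cytokines, subject)
    net.edges.to_csv(OUT / f"edges_{subject}.tsv", sep="\t", index=False)
    net.nodes.to_csv(OUT / f"nodes_{subject}.tsv", sep="\t")
    cross = net.edges[
        net.edges.apply(
            lambda e: net.nodes.loc[e.node_a, "kind"]
            != net.nodes.loc[e.node_b, "kind"],
            axis=1,
        )
    ] if len(net.edges) else net.edges
    print(f"subject {subject}: {len(net.nodes)} nodes, {len(net.edges)} edges "
          f"({len(cross)} genus-cytokine)")
    for _, e in cross.iterrows():
        flag = "*" if e.significant else " "
        print(f"    {e.node_a} -- {e.node_b}: rho={e.rho:+.2f} "
              f"p={e.p:.3g} q={e.q:.3g}{flag}")
print(f"wrote edge/node lists under {OUT}/")
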