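#!/usr/bin/env python
"""Pool the per-region networks per group by random-effects meta-analysis.

Edges are pooled on the Fisher-z scale with DerSimonian-Laird between-region
variance and flagged at BH FDR < 0.05 within each group. Writes
results/meta_{hyp,nonhyp}.tsv plus GraphML snapshots of the significant
networks, and prints the network summaries (counts, mean degree, % negative,
per-phylum participation).
"""

import argparse
from pathlib import Path

import pandas as pd

from coabnet.data import read_taxonomy
from coabnet.meta import meta_network, network_summary, to_graphml
from coabnet.pipeline import edge_overlap

parser = argparse.ArgumentParser()
parser.add_argument("--networks", default="results/networks")
parser.add_argument("--cohort", default="results/cohort")
parser.add_argument("--out", default="results")
args = parser.parse_args()

taxonomy = read_taxonomy(Path(args.cohort) / "taxonomy.tsv")
out = Path(args.out)
pooled = {}
for group in ("hyp", "nonhyp"):
    files = sorted(Path(args.networks).glob(f"edges_{group}_*.tsv"))
    strata = {f.stem: pd.read_csv(f, sep="\t") for f in files}
    pooled[group] = meta_network(strata)
    pooled[group].to_csv(out / f"meta_{group}.tsv", sep="\t", index=False)
    sig = pooled[group][pooled[group]["significant"]]
    if len(sig):
        to_graphml(sig, out / f"network_{group}.graphml")
    s = network_summary(sig, taxonomy)
    print(f"\n{group}: {s['n_edges']} significant edges over {s['n_nodes']} genera")
    print(f"  mean degree {s['mean_degree']:.1f}, {s['pct_negative']:.1f}% negative")
    for ph, pct in sorted(s["phylum_edge_pct"].items(), key=lambda kv: -kv[1])[:3]:
        print(f"  {ph}: {pct:.0f}% of edges")

ov = edge_overlap(pooled["hyp"][pooled["hyp"]["significant"]],
                  pooled["nonhyp"][pooled["nonhyp"]["significant"]])
print(f"\nunion across groups: {ov['n_union']} unique edges "
      f"({ov['n_a']} + {ov['n_b']} - {ov['n_intersection']} shared)")
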