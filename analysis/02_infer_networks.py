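#!/usr/bin/env python
"""Rarefy, filter, and fit per-stratum latent-correlation networks.

Reads the cohort from results/cohort/, rarefies to 10,000 reads, keeps
genera with >= 10% prevalence, and fits the penalized compositional
estimator separately in every region x group stratum (hypertensive vs
non-hypertensive). Writes one edge table per stratum under
results/networks/.
"""

import argparse
import warnings
from pathlib import Path

from coabnet.data import CountTable, prevalence_filter, rarefy, read_metadata, read_taxonomy
from coabnet.pipeline import fit_stratum_edges

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", default="results/cohort")
parser.add_argument("--out", default="results/networks")
parser.add_argument("--lam", type=float, default=0.01)
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

cohort = Path(args.cohort)
table = CountTable.from_tsv(cohort / "counts.tsv", read_taxonomy(cohort / "taxonomy.tsv"))
metadata = read_metadata(cohort / "metadata.tsv")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = prevalence_filter(rarefy(table, 10_000, seed=args.seed), 0.10)
metadata = metadata.loc[table.sample_ids]
print(f"after rarefaction + prevalence filter: {table.n_samples} samples, "
      f"{table.n_genera} genera")

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
for (region, hyp), ids in metadata.groupby(["region", "hypertension"]).groups.items():
    group = "hyp" if hyp else "nonhyp"
    edges = fit_stratum_edges(table.subset_samples(ids), lam=args.lam)
    path = out / f"edges_{group}_{region}.tsv"
    edges.to_csv(path, sep="\t", index=False)
    print(f"{group:7s} {region}: n={len(ids):4d}, {len(edges)} pairs -> {path.name}")
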