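"""End-to-end orchestration: simulate/load -> networks -> meta -> differential
-> covariate adjustment -> severity -> pathway interaction variance -> report.

Each stage writes plain TSV/JSON under the output directory before the next
stage starts, so the pipeline is resumable and every tally in the summary
report can be recounted from the stage files. Identical config + seed gives
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as dmod
from .cclasso import DEFAULT_LAMBDA, bootstrap_edges, fit_latent_correlation, select_lambda
from .data import CountTable, prevalence_filter, rarefy, transform_features
from .differential import adjust_partial_correlation, cochran_q_between, differential_edges
from .interaction import fit_interactions_by_grade, pathway_screen, variance_trend
from .meta import meta_network, network_summary, to_graphml
from .severity import differential_abundance, grade_heterogeneity, grade_networks
from .simulate import SimulationConfig, simulate_cohort, write_cohort


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis reproducibly."""

    simulate: SimulationConfig | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    pathways_path: str | None = None
    rarefaction_depth: int = 10_000
    min_prevalence: float = 0.10
    lam: float | str = DEFAULT_LAMBDA  # a float, or "auto" for CV selection
    bootstrap_b: int = 100
    fdr_threshold: float = 0.05
    i2_threshold: float = 75.0
    het_p_threshold: float = 0.05
    min_stratum_n: int = 20
    k_min: int = 2
    seed: int = 0
    outdir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            sim = {k: (tuple(map(tuple, v)) if isinstance(v, list) and v and
                       isinstance(v[0], list) else (tuple(v) if isinstance(v, list) else v))
                   for k, v in sim.items()}
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.simulate).items()
            }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def fit_stratum_edges(
    table: CountTable,
    lam: float = DEFAULT_LAMBDA,
    bootstrap_b: int = 0,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Edge estimates for one stratum (region x group or region x grade).

    Genera with no reads in the stratum are dropped for that stratum only.
    With ``bootstrap_b`` >= 2 the bootstrap SEs/p-values are attached;
    otherwise only the point estimates (which is all the downstream
    meta-analysis consumes).
    """
    present = table.genus_ids[(table.counts > 0).any(axis=0)]
    sub = CountTable(table.counts[present], table.taxonomy)
    if bootstrap_b >= 2:
        return bootstrap_edges(sub, lam=lam, B=bootstrap_b, seed=seed, **fit_kwargs)
    model = fit_latent_correlation(sub, lam=lam, **fit_kwargs)
    p = sub.n_genera
    iu = np.triu_indices(p, k=1)
    return pd.DataFrame(
        {
            "genus_i": sub.genus_ids[iu[0]],
            "genus_j": sub.genus_ids[iu[1]],
            "r": model.rho[iu],
            "n": sub.n_samples,
        }
    )


def edge_overlap(edges_a: pd.DataFrame, edges_b: pd.DataFrame) -> dict:
    """Set algebra over unordered genus-pair keys: |A|, |B|, |A n B|, |A u B|."""

    def keyset(df):
        return {tuple(sorted((r.genus_i, r.genus_j))) for r in df.itertuples(index=False)}

    a, b = keyset(edges_a), keyset(edges_b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(a & b),
        "n_union": len(a | b),
    }


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the summary report (also written
    to ``report.json`` in the output directory)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- stage 1: inputs -------------------------------------------------
    if config.simulate is not None:
        table, metadata, pathways, manifest = simulate_cohort(config.simulate)
        write_cohort(out / "cohort", table, metadata, pathways, manifest)
    else:
        if not (config.counts_path and config.metadata_path):
            raise dmod.ValidationError("either a simulate block or input paths required")
        taxonomy = (
            dmod.read_taxonomy(config.taxonomy_path)
            if config.taxonomy_path
            else pd.Series(dtype=object)
        )
        table = CountTable.from_tsv(config.counts_path, taxonomy)
        metadata = dmod.read_metadata(config.metadata_path)
        pathways = (
            pd.read_csv(config.pathways_path, sep="\t", index_col=0)
            if config.pathways_path
            else pd.DataFrame(index=table.sample_ids)
        )

    # --- stage 2: rarefy + prevalence filter ------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = rarefy(table, depth=config.rarefaction_depth, seed=config.seed)
    table = prevalence_filter(table, config.min_prevalence)
    metadata = metadata.loc[table.sample_ids]
    pathways = pathways.loc[table.sample_ids]
    table.to_tsv(out / "filtered_counts.tsv")

    lam = config.lam
    if lam == "auto":
        lam = select_lambda(
            table, grid=np.geomspace(1e-3, 0.3, 6), seed=config.seed
        )
    lam = float(lam)

    # --- stage 3: per-stratum networks and per-group meta ------------------
    nets_dir = out / "networks"
    nets_dir.mkdir(exist_ok=True)
    group_meta = {}
    group_edges: dict[str, dict[str, pd.DataFrame]] = {}
    for group, mask in [
        ("hyp", metadata["hypertension"] == 1),
        ("nonhyp", metadata["hypertension"] == 0),
    ]:
        strata = {}
        grp_meta = metadata.loc[mask.index[mask]]
        for region, ids in grp_meta.groupby("region").groups.items():
            if len(ids) >= config.min_stratum_n:
                strata[str(region)] = table.subset_samples(ids)
        if not strata:
            raise dmod.ValidationError(f"group {group}: no usable region stratum")
        edges = {}
        for name in sorted(strata):
            e = fit_stratum_edges(
                strata[name],
                lam=lam,
                bootstrap_b=config.bootstrap_b,
                seed=config.seed,
            )
            _write(e, nets_dir / f"edges_{group}_{name}.tsv")
            edges[name] = e
        group_edges[group] = edges
        pooled = meta_network(
            edges, fdr_threshold=config.fdr_threshold, k_min=min(config.k_min, len(edges))
        )
        _write(pooled, out / f"meta_{group}.tsv")
        sig = pooled[pooled["significant"]]
        if len(sig):
            to_graphml(sig, out / f"network_{group}.graphml")
        group_meta[group] = pooled

    summaries = {
        group: network_summary(
            df[df["significant"]], table.taxonomy, nodes=table.genus_ids
        )
        for group, df in group_meta.items()
    }

    # --- stage 4: differential edges ---------------------------------------
    diff = differential_edges(
        group_meta["hyp"],
        group_meta["nonhyp"],
        i2_threshold=config.i2_threshold,
        p_threshold=config.het_p_threshold,
    )
    _write(diff, out / "differential.tsv")
    het = diff[diff["heterogeneous"]]

    # --- stage 5: covariate adjustment of differential edges ---------------
    adj_consistent_frac = float("nan")
    if len(het):
        genus_features = transform_features(
            pd.DataFrame(
                table.counts.to_numpy(dtype=float) / config.rarefaction_depth,
                index=table.sample_ids,
                columns=table.genus_ids,
            ),
            metadata,
        )
        hyp_meta = metadata[metadata["hypertension"] == 1]
        feats_by_stratum = {
            str(region): genus_features.loc[ids]
            for region, ids in hyp_meta.groupby("region").groups.items()
            if len(ids) >= config.min_stratum_n
        }
        adjusted = adjust_partial_correlation(het, feats_by_stratum, metadata)
        _write(adjusted, out / "adjusted_edges.tsv")
        if len(adjusted):
            adj_by_stratum = {
                s: g.drop(columns="stratum") for s, g in adjusted.groupby("stratum")
            }
            adj_meta = meta_network(adj_by_stratum, k_min=1)
            _write(adj_meta, out / "adjusted_meta.tsv")
            merged = het.merge(adj_meta, on=["genus_i", "genus_j"], suffixes=("", "_adj"))
            cons = []
            for row in merged.itertuples(index=False):
                _, _, p_c, _ = cochran_q_between(
                    [row.z_case, row.pooled_z], [row.se_case, row.se]
                )
                cons.append(p_c > config.het_p_threshold)
            merged["adjustment_consistent"] = cons
            _write(
                merged[["genus_i", "genus_j", "z_case", "pooled_z",
                        "adjustment_consistent"]],
                out / "adjustment_consistency.tsv",
            )
            adj_consistent_frac = float(np.mean(cons)) if cons else float("nan")

    # --- stage 6: severity ---------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g_nets = grade_networks(
            table,
            metadata,
            min_stratum_n=config.min_stratum_n,
            lam=lam,
            k_min=config.k_min,
            fdr_threshold=config.fdr_threshold,
            combined_fallback=True,
        )
    for g, df in g_nets.items():
        _write(df, out / f"meta_grade{g}.tsv")
    sev = grade_heterogeneity(
        g_nets,
        candidate_edges=het if len(het) else None,
        i2_threshold=config.i2_threshold,
        p_threshold=config.het_p_threshold,
    )
    _write(sev, out / "severity_edges.tsv")

    # --- stage 7: differential abundance + interaction variance -------------
    genus_rel = pd.DataFrame(
        table.counts.to_numpy(dtype=float) / config.rarefaction_depth,
        index=table.sample_ids,
        columns=table.genus_ids,
    )
    genus_t = transform_features(genus_rel, metadata)
    genus_two = differential_abundance(
        genus_t, metadata, "two_group", config.fdr_threshold
    )
    _write(genus_two, out / "genus_diff_two_group.tsv")

    trend = pd.DataFrame()
    fits = pd.DataFrame()
    screened: list = []
    if pathways.shape[1] > 0:
        pw_t = transform_features(pathways, metadata)
        pw_two = differential_abundance(pw_t, metadata, "two_group", config.fdr_threshold)
        pw_four = differential_abundance(pw_t, metadata, "four_grade", config.fdr_threshold)
        _write(pw_two, out / "pathway_diff_two_group.tsv")
        _write(pw_four, out / "pathway_diff_four_grade.tsv")
        screened = pathway_screen(pw_two, pw_four, config.fdr_threshold)
        sev_pairs = [
            (r.genus_i, r.genus_j)
            for r in sev.itertuples(index=False)
            if getattr(r, "severity_associated", False)
        ]
        if screened and sev_pairs:
            fits = fit_interactions_by_grade(
                pw_t, genus_t, metadata, sev_pairs, pathway_ids=screened
            )
            _write(fits, out / "interaction_fits.tsv")
            if len(fits):
                trend = variance_trend(fits, config.het_p_threshold)
                _write(trend, out / "variance_trend.tsv")

    # --- stage 8: report ------------------------------------------------------
    overlap = edge_overlap(
        group_meta["hyp"][group_meta["hyp"]["significant"]],
        group_meta["nonhyp"][group_meta["nonhyp"]["significant"]],
    )
    class_counts = het["class"].value_counts().to_dict() if len(het) else {}
    report = {
        "n_samples": int(table.n_samples),
        "n_genera": int(table.n_genera),
        "lambda": lam,
        "significant_edges": {
            g: int(df["significant"].sum()) for g, df in group_meta.items()
        },
        "network_summary": {
            g: {
                "n_nodes": s["n_nodes"],
                "n_edges": s["n_edges"],
                "mean_degree": s["mean_degree"],
                "pct_negative": s["pct_negative"],
                "phylum_edge_pct": s["phylum_edge_pct"],
            }
            for g, s in summaries.items()
        },
        "edge_overlap": overlap,
        "differential": {
            "tested": int(len(diff)),
            "heterogeneous": int(len(het)),
            "by_class": {k: int(v) for k, v in class_counts.items()},
        },
        "adjustment_consistent_fraction": adj_consistent_frac,
        "severity": {
            "tested": int(len(sev)),
            "heterogeneous": int(sev["heterogeneous"].sum()) if len(sev) else 0,
            "severity_associated": int(sev["severity_associated"].sum()) if len(sev) else 0,
        },
        "pathways": {
            "screened": len(screened),
            "interaction_fits": int(len(fits)),
            "interaction_significant": int((fits["q"] < config.fdr_threshold).sum())
            if len(fits)
            else 0,
            "trend_significant": int(trend["significant"].sum()) if len(trend) else 0,
        },
        "seed": config.seed,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
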