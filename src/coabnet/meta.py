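"""Random-effects meta-analysis of per-region co-abundance networks.

Each region contributes an estimated correlation per genus pair. Correlations
are pooled on the Fisher-z scale (atanh) with sampling variance 1/(n-3), the
classical convention for correlation meta-analysis. Between-region variance
tau^2 uses the DerSimonian-Laird moment estimator; edge-wise p-values are
corrected across all pairs jointly by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ValidationError


def fisher_z(r):
    """Variance-stabilizing Fisher transform atanh(r); requires |r| < 1."""
    r_arr = np.asarray(r, dtype=float)
    if (np.abs(r_arr) >= 1).any():
        raise ValidationError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def inverse_fisher_z(z):
    return np.tanh(z)


@dataclass
class PooledEffect:
    """DerSimonian-Laird pooled effect for one edge."""

    pooled_z: float
    pooled_se: float
    tau2: float
    Q: float
    I2: float
    p: float
    K: int


def pool_random_effects(z, v) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling of Fisher-z effects.

    Fixed weights w = 1/v give Q = sum w (z - zbar_w)^2 and the moment
    estimator tau^2 = max(0, (Q - (K-1)) / (sum w - sum w^2 / sum w)); the
    pooled effect then re-weights by w* = 1/(v + tau^2). With a single
    stratum the input is returned unchanged (tau^2 = Q = 0).
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)
    if z.shape != v.shape or z.ndim != 1:
        raise ValidationError("z and v must be 1-d and of equal length")
    K = z.size
    if K == 0:
        raise ValidationError("no strata to pool")
    if (v <= 0).any():
        raise ValidationError("variances must be positive")
    if K == 1:
        se = float(np.sqrt(v[0]))
        p = 2 * stats.norm.sf(abs(z[0]) / se)
        return PooledEffect(float(z[0]), se, 0.0, 0.0, 0.0, float(p), 1)
    w = 1.0 / v
    zbar = float(np.sum(w * z) / np.sum(w))
    Q = float(np.sum(w * (z - zbar) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (K - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * z) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    p = 2 * stats.norm.sf(abs(pooled) / se)
    I2 = max(0.0, (Q - (K - 1)) / Q) * 100 if Q > 0 else 0.0
    return PooledEffect(pooled, se, tau2, Q, I2, float(p), K)


def bh_fdr(p):
    """Benjamini-Hochberg step-up q-values, capped at 1 and order-preserving."""
    p_arr = np.asarray(p, dtype=float)
    if p_arr.size == 0:
        return p_arr.copy()
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p_arr, method="fdr_bh")[1]


def meta_network(
    edges_by_stratum: dict[str, pd.DataFrame],
    fdr_threshold: float = 0.05,
    k_min: int = 2,
) -> pd.DataFrame:
    """Pool per-stratum edge estimates into one network with BH FDR.

    Parameters
    ----------
    edges_by_stratum
        Mapping stratum -> DataFrame with columns genus_i, genus_j, r, n.
    fdr_threshold
        q-value cutoff for the ``significant`` flag.
    k_min
        Minimum number of strata an edge must be estimable in to be pooled
        (pairs seen in fewer strata are dropped; single-stratum analyses
        should pass k_min=1, which reduces to a per-stratum z-test).

    Returns a DataFrame with one row per pooled edge: K, pooled_r, pooled_z,
    se, tau2, Q, I2, p, q, significant.
    """
    frames = []
    for stratum, df in edges_by_stratum.items():
        sub = df[["genus_i", "genus_j", "r", "n"]].copy()
        sub["stratum"] = stratum
        frames.append(sub)
    if not frames:
        raise ValidationError("no strata provided")
    pooled_input = pd.concat(frames, ignore_index=True)
    # canonical unordered pair key
    swap = pooled_input["genus_i"] > pooled_input["genus_j"]
    pooled_input.loc[swap, ["genus_i", "genus_j"]] = pooled_input.loc[
        swap, ["genus_j", "genus_i"]
    ].to_numpy()

    records = []
    for (gi, gj), grp in pooled_input.groupby(["genus_i", "genus_j"], sort=True):
        if len(grp) < k_min:
            continue
        r = np.clip(grp["r"].to_numpy(), -0.999999, 0.999999)
        n = grp["n"].to_numpy(dtype=float)
        if (n <= 3).any():
            raise ValidationError("stratum sample size must exceed 3")
        pooled = pool_random_effects(fisher_z(r), 1.0 / (n - 3))
        records.append(
            {
                "genus_i": gi,
                "genus_j": gj,
                "K": pooled.K,
                "pooled_r": float(inverse_fisher_z(pooled.pooled_z)),
                "pooled_z": pooled.pooled_z,
                "se": pooled.pooled_se,
                "tau2": pooled.tau2,
                "Q": pooled.Q,
                "I2": pooled.I2,
                "p": pooled.p,
            }
        )
    if not records:
        raise ValidationError(f"no edge estimable in >= {k_min} strata")
    out = pd.DataFrame.from_records(records)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_threshold
    return out


def network_summary(
    edges: pd.DataFrame, taxonomy: pd.Series, nodes=None
) -> dict:
    """Descriptive summary of a significant co-abundance network.

    Reports node and edge counts, mean degree 2E/N, per-genus degrees,
    per-phylum participation (a phylum participates in an edge if at least
    one endpoint belongs to it), and the share of negative edges.
    """
    if nodes is None:
        nodes = pd.Index(
            sorted(set(edges["genus_i"]).union(edges["genus_j"]))
        )
    else:
        nodes = pd.Index(nodes)
    n_nodes = len(nodes)
    n_edges = len(edges)
    degree = pd.Series(0, index=nodes, dtype=int)
    if n_edges:
        cnt_i = edges["genus_i"].value_counts()
        cnt_j = edges["genus_j"].value_counts()
        degree = degree.add(cnt_i, fill_value=0).add(cnt_j, fill_value=0).astype(int)
    mean_degree = 2 * n_edges / n_nodes if n_nodes else float("nan")

    phylum_genus_pct: dict[str, float] = {}
    phylum_edge_pct: dict[str, float] = {}
    if len(taxonomy) and n_nodes:
        phyla = taxonomy.reindex(nodes)
        for ph in sorted(phyla.dropna().unique()):
            members = set(nodes[phyla == ph])
            phylum_genus_pct[ph] = 100.0 * len(members) / n_nodes
            if n_edges:
                touch = (
                    edges["genus_i"].isin(members) | edges["genus_j"].isin(members)
                ).sum()
                phylum_edge_pct[ph] = 100.0 * touch / n_edges

    value_col = "pooled_r" if "pooled_r" in edges.columns else "r"
    pct_negative = (
        100.0 * (edges[value_col] < 0).sum() / n_edges if n_edges else float("nan")
    )
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "mean_degree": mean_degree,
        "degree": degree,
        "phylum_genus_pct": phylum_genus_pct,
        "phylum_edge_pct": phylum_edge_pct,
        "pct_negative": pct_negative,
    }


def to_graphml(edges: pd.DataFrame, path, weight_col: str = "pooled_r") -> None:
    """Write a significant-edge network as GraphML with the correlation as weight."""
    import networkx as nx

    G = nx.Graph()
    for row in edges.itertuples(index=False):
        G.add_edge(row.genus_i, row.genus_j, weight=float(getattr(row, weight_col)))
    nx.write_graphml(G, path)
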