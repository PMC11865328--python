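"""Differential co-abundance edges between conditions.

Two pooled networks (e.g. hypertensive vs non-hypertensive) are compared edge
by edge with Cochran's Q on the pooled Fisher-z effects. Edges with I^2 > 75%
and Q-test p < 0.05 are called heterogeneous (differential) and classified as
increased / decreased / reversed from the sign and magnitude of the two
effects. Covariate influence is removed by partial correlation against the
8 host covariates; replication compares the pooled primary effect against an
independent cohort's estimate with the same Q machinery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import COVARIATE_COLUMNS, ValidationError
from .meta import fisher_z, pool_random_effects

I2_THRESHOLD = 75.0
P_THRESHOLD = 0.05


def cochran_q_between(effects, ses):
    """Cochran's Q heterogeneity test across effect estimates.

    Returns (Q, df, p, I2) with inverse-variance weights w = 1/se^2,
    df = K - 1, p from the upper chi-square tail, and
    I2 = max(0, (Q - df)/Q) * 100.
    """
    theta = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.size < 2:
        raise ValidationError("heterogeneity needs at least 2 effects")
    if (se <= 0).any():
        raise ValidationError("standard errors must be positive")
    w = 1.0 / se**2
    theta_bar = np.sum(w * theta) / np.sum(w)
    Q = float(np.sum(w * (theta - theta_bar) ** 2))
    df = theta.size - 1
    p = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) * 100 if Q > 0 else 0.0
    return Q, df, p, I2


def classify_differential(z_case, z_control, sig_case, sig_control) -> str:
    """Direction-of-change class for a heterogeneous edge.

    ``reversed`` when the two pooled effects disagree in sign; otherwise
    ``increased`` when |z_case| > |z_control| and ``decreased`` when not.
    Significance flags are carried by the caller to reproduce sub-tallies
    (e.g. increased edges significant only in the case group).
    """
    if np.sign(z_case) != np.sign(z_control) and z_case != 0 and z_control != 0:
        return "reversed"
    return "increased" if abs(z_case) > abs(z_control) else "decreased"


def differential_edges(
    meta_case: pd.DataFrame,
    meta_control: pd.DataFrame,
    i2_threshold: float = I2_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    universe: str = "union_significant",
) -> pd.DataFrame:
    """Compare two pooled networks edge-wise with Cochran's Q.

    Parameters
    ----------
    meta_case, meta_control
        Pooled networks (``meta_network`` output) for the two conditions.
    universe
        ``union_significant`` restricts the test to edges significant in at
        least one condition (the Fig-style union set); ``all`` tests every
        edge pooled in both conditions.

    Returns one row per tested edge with Q, I2, p_het, the heterogeneity
    flag, and the change class for flagged edges.
    """
    key = ["genus_i", "genus_j"]
    a = meta_case.set_index(key)
    b = meta_control.set_index(key)
    common = a.index.intersection(b.index)
    if universe == "union_significant":
        keep = [
            k
            for k in common
            if bool(a.loc[k, "significant"]) or bool(b.loc[k, "significant"])
        ]
        common = pd.MultiIndex.from_tuples(keep, names=key) if keep else common[:0]
    elif universe != "all":
        raise ValidationError(f"unknown universe: {universe}")

    records = []
    for gi, gj in common:
        za, sa = a.loc[(gi, gj), ["pooled_z", "se"]]
        zb, sb = b.loc[(gi, gj), ["pooled_z", "se"]]
        Q, df, p, I2 = cochran_q_between([za, zb], [sa, sb])
        het = (I2 > i2_threshold) and (p < p_threshold)
        sig_a = bool(a.loc[(gi, gj), "significant"])
        sig_b = bool(b.loc[(gi, gj), "significant"])
        records.append(
            {
                "genus_i": gi,
                "genus_j": gj,
                "z_case": float(za),
                "se_case": float(sa),
                "z_control": float(zb),
                "se_control": float(sb),
                "Q": Q,
                "I2": I2,
                "p_het": p,
                "heterogeneous": het,
                "class": classify_differential(za, zb, sig_a, sig_b) if het else "",
                "sig_case": sig_a,
                "sig_control": sig_b,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "genus_i",
            "genus_j",
            "z_case",
            "se_case",
            "z_control",
            "se_control",
            "Q",
            "I2",
            "p_het",
            "heterogeneous",
            "class",
            "sig_case",
            "sig_control",
        ],
    )


def partial_correlation_matrix(R: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Partial correlations from a correlation matrix via its precision matrix.

    pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with Omega = R^-1.
    A singular input is regularized by adding ``ridge`` to the diagonal
    (with a warning).
    """
    R = np.asarray(R, dtype=float)
    try:
        Omega = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; adding ridge", stacklevel=2)
        Omega = np.linalg.inv(R + ridge * np.eye(R.shape[0]))
    d = np.sqrt(np.diag(Omega))
    pcor = -Omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def adjust_partial_correlation(
    edges: pd.DataFrame,
    features_by_stratum: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    covariates=COVARIATE_COLUMNS,
) -> pd.DataFrame:
    """Covariate-adjusted edge correlations per stratum via partial correlation.

    For each edge and each stratum, the Pearson correlation matrix of
    (genus_i, genus_j, covariates) on transformed abundances is inverted and
    the (i, j) partial correlation replaces the marginal estimate. Output has
    the same shape as a per-stratum edge table and can be re-pooled with
    ``meta_network`` and compared to the unadjusted pooled effects with
    ``cochran_q_between``.
    """
    records = []
    for stratum, feats in features_by_stratum.items():
        meta = metadata.loc[feats.index]
        X_cov = meta[list(covariates)].to_numpy(dtype=float)
        n = len(feats)
        for row in edges.itertuples(index=False):
            gi, gj = row.genus_i, row.genus_j
            if gi not in feats.columns or gj not in feats.columns:
                continue
            block = np.column_stack(
                [feats[gi].to_numpy(), feats[gj].to_numpy(), X_cov]
            )
            sd = block.std(axis=0)
            keep = sd > 0
            keep[:2] = True  # the genus pair always enters
            R = np.corrcoef(block[:, keep], rowvar=False)
            pcor = partial_correlation_matrix(R)
            records.append(
                {"genus_i": gi, "genus_j": gj, "r": float(pcor[0, 1]), "n": n,
                 "stratum": stratum}
            )
    if not records:
        warnings.warn("no edges adjustable in any stratum", stacklevel=2)
    return pd.DataFrame.from_records(
        records, columns=["genus_i", "genus_j", "r", "n", "stratum"]
    )


def compare_replication(
    primary: pd.DataFrame,
    replication_by_cohort: dict[str, pd.DataFrame],
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Replication report of primary-significant edges in independent cohorts.

    Replication cohorts are pooled into a single effect per edge with the
    same random-effects machinery (k_min=1 so a single cohort suffices). An
    edge is ``replicated`` when the replication effect is significant at
    ``p_threshold`` with the same sign, and ``consistent`` when Cochran's Q
    between the primary and replication pooled effects has p > threshold.
    """
    from .meta import meta_network

    sig = primary[primary["significant"]]
    if sig.empty:
        warnings.warn("no significant primary edges to replicate", stacklevel=2)
        return pd.DataFrame(
            columns=["genus_i", "genus_j", "z_primary", "z_replication",
                     "p_replication", "p_consistency", "replicated", "consistent"]
        )
    rep_pooled = meta_network(replication_by_cohort, k_min=1)
    rep = rep_pooled.set_index(["genus_i", "genus_j"])
    records = []
    for row in sig.itertuples(index=False):
        key = (row.genus_i, row.genus_j)
        if key not in rep.index:
            continue
        rrow = rep.loc[key]
        _, _, p_cons, _ = cochran_q_between(
            [row.pooled_z, rrow["pooled_z"]], [row.se, rrow["se"]]
        )
        replicated = (rrow["p"] < p_threshold) and (
            np.sign(rrow["pooled_z"]) == np.sign(row.pooled_z)
        )
        records.append(
            {
                "genus_i": row.genus_i,
                "genus_j": row.genus_j,
                "z_primary": row.pooled_z,
                "z_replication": float(rrow["pooled_z"]),
                "p_replication": float(rrow["p"]),
                "p_consistency": p_cons,
                "replicated": bool(replicated),
                "consistent": p_cons > p_threshold,
            }
        )
    if not records:
        warnings.warn("no overlapping edges between primary and replication",
                      stacklevel=2)
    return pd.DataFrame.from_records(
        records,
        columns=["genus_i", "genus_j", "z_primary", "z_replication",
                 "p_replication", "p_consistency", "replicated", "consistent"],
    )
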