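"""Severity-stratified networks, grade heterogeneity, and trend statistics.

Hypertension severity is graded 0-3 from blood pressure. Co-abundance
networks are inferred per grade (region-stratified, then pooled), the
candidate differential edges are tested for heterogeneity across the four
grade networks (Cochran's Q, df = 3), and edges whose pooled strength moves
systematically with severity are identified by a weighted linear regression
of the pooled Fisher-z effect on the numeric grade 0-3.

Differential abundance of single features (genera or pathways) uses the
classical nonparametric battery on inverse-rank-transformed, covariate-
residualized values: Wilcoxon rank-sum for two groups, Kruskal-Wallis plus a
Spearman trend across the four grades, with BH FDR per feature family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cclasso import DEFAULT_LAMBDA
from .data import CountTable, ValidationError
from .differential import I2_THRESHOLD, P_THRESHOLD, cochran_q_between
from .meta import bh_fdr, meta_network


def severity_trend(z, se=None, grades=None, weighted: bool = True):
    """Linear trend of pooled edge strength across hypertension grades.

    Weighted least squares of pooled z on the numeric grade with weights
    1/se^2 (plain OLS when ``weighted`` is False or no SEs are given).
    Returns (slope, slope_se, p) from the slope t-test with k-2 df.
    """
    z = np.asarray(z, dtype=float)
    k = z.size
    if k < 3:
        raise ValidationError("trend needs at least 3 grade effects")
    x = np.asarray(grades, dtype=float) if grades is not None else np.arange(k, dtype=float)
    if se is not None and weighted:
        w = 1.0 / np.asarray(se, dtype=float) ** 2
    else:
        w = np.ones(k)
    W = np.diag(w)
    X = np.column_stack([np.ones(k), x])
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ z)
    resid = z - X @ beta
    dof = k - 2
    s2 = float(resid @ (w * resid)) / dof
    cov = s2 * np.linalg.inv(XtWX)
    slope = float(beta[1])
    slope_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if slope_se == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2 * stats.t.sf(abs(slope / slope_se), dof)
    return slope, slope_se, float(p)


def grade_networks(
    table: CountTable,
    metadata: pd.DataFrame,
    grades=(0, 1, 2, 3),
    min_stratum_n: int = 20,
    lam: float = DEFAULT_LAMBDA,
    k_min: int = 2,
    fdr_threshold: float = 0.05,
    combined_fallback: bool = False,
    **fit_kwargs,
) -> dict[int, pd.DataFrame]:
    """Pooled co-abundance network per hypertension grade.

    Within each grade, every region stratum with at least ``min_stratum_n``
    samples is fitted separately and the per-region estimates pooled by
    random-effects meta-analysis. With ``combined_fallback`` a grade whose
    regions are all below the floor is fitted on its combined samples as a
    single stratum; otherwise such a grade raises an error naming it.
    """
    from .pipeline import fit_stratum_edges

    meta_aligned = metadata.loc[table.sample_ids]
    out: dict[int, pd.DataFrame] = {}
    for grade in grades:
        in_grade = meta_aligned.index[meta_aligned["grade"] == grade]
        strata = {}
        for region, ids in meta_aligned.loc[in_grade].groupby("region").groups.items():
            if len(ids) >= min_stratum_n:
                strata[str(region)] = table.subset_samples(ids)
        if not strata:
            if combined_fallback and len(in_grade) >= min_stratum_n:
                strata = {"combined": table.subset_samples(in_grade)}
            else:
                raise ValidationError(
                    f"grade {grade}: no region stratum with n >= {min_stratum_n}"
                )
        edges = {
            name: fit_stratum_edges(sub, lam=lam, **fit_kwargs)
            for name, sub in strata.items()
        }
        out[grade] = meta_network(
            edges, fdr_threshold=fdr_threshold, k_min=min(k_min, len(edges))
        )
    return out


def grade_heterogeneity(
    grade_meta: dict[int, pd.DataFrame],
    candidate_edges: pd.DataFrame | None = None,
    i2_threshold: float = I2_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    trend_p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Heterogeneity across grade networks and the severity trend per edge.

    For every edge estimable in at least two grades (restricted to
    ``candidate_edges`` when given — the differential-edge funnel), computes
    Cochran's Q over the per-grade pooled effects, the I^2 share, and, when
    at least three grades are estimable, the weighted trend of strength on
    grade. Flags ``heterogeneous`` (I^2 and p thresholds) and
    ``severity_associated`` (heterogeneous and trend p below threshold).
    """
    grades = sorted(grade_meta)
    indexed = {g: df.set_index(["genus_i", "genus_j"]) for g, df in grade_meta.items()}
    if candidate_edges is not None:
        keys = list(
            pd.MultiIndex.from_frame(candidate_edges[["genus_i", "genus_j"]])
        )
    else:
        keys = sorted(set().union(*(set(df.index) for df in indexed.values())))
    records = []
    for key in keys:
        zs, ses, gs = [], [], []
        for g in grades:
            if key in indexed[g].index:
                zs.append(float(indexed[g].loc[key, "pooled_z"]))
                ses.append(float(indexed[g].loc[key, "se"]))
                gs.append(g)
        if len(zs) < 2:
            continue
        Q, df, p_het, I2 = cochran_q_between(zs, ses)
        het = (I2 > i2_threshold) and (p_het < p_threshold)
        if len(zs) >= 3:
            slope, slope_se, p_trend = severity_trend(zs, ses, grades=gs)
        else:
            slope, slope_se, p_trend = np.nan, np.nan, np.nan
        rec = {"genus_i": key[0], "genus_j": key[1]}
        for g in grades:
            if g in gs:
                i = gs.index(g)
                rec[f"z_g{g}"], rec[f"se_g{g}"] = zs[i], ses[i]
            else:
                rec[f"z_g{g}"], rec[f"se_g{g}"] = np.nan, np.nan
        rec.update(
            {
                "K_grades": len(zs),
                "Q": Q,
                "I2": I2,
                "p_het": p_het,
                "heterogeneous": het,
                "slope": slope,
                "slope_se": slope_se,
                "trend_p": p_trend,
                "severity_associated": bool(
                    het and np.isfinite(p_trend) and p_trend < trend_p_threshold
                ),
            }
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def differential_abundance(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "two_group",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Nonparametric differential tests per feature column.

    ``features`` must already be inverse-rank transformed and residualized
    (see :func:`coabnet.data.transform_features`). ``two_group`` runs a
    Wilcoxon rank-sum test of hypertensive vs non-hypertensive;
    ``four_grade`` runs Kruskal-Wallis across grades 0-3 plus a Spearman
    correlation of the residuals with the numeric grade. BH FDR is applied
    across the features of this call (one feature family per call).
    """
    meta = metadata.loc[features.index]
    if mode == "two_group":
        groups = [meta["hypertension"] == 1, meta["hypertension"] == 0]
        group_labels = ["hyp", "nonhyp"]
    elif mode == "four_grade":
        groups = [meta["grade"] == g for g in (0, 1, 2, 3)]
        group_labels = [f"g{g}" for g in (0, 1, 2, 3)]
    else:
        raise ValidationError(f"unknown mode: {mode}")
    if any(int(g.sum()) == 0 for g in groups):
        raise ValidationError("empty group in differential abundance")

    records = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        parts = [x[g.to_numpy()] for g in groups]
        rec: dict = {"feature": col}
        if np.all(x == x[0]):
            rec.update({"statistic": np.nan, "p": 1.0, "constant": True})
        else:
            rec["constant"] = False
            if mode == "two_group":
                res = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided")
                rec["statistic"], rec["p"] = float(res.statistic), float(res.pvalue)
            else:
                res = stats.kruskal(*parts)
                rec["statistic"], rec["p"] = float(res.statistic), float(res.pvalue)
        for lbl, part in zip(group_labels, parts):
            rec[f"median_{lbl}"] = float(np.median(part)) if part.size else np.nan
        if mode == "four_grade":
            if rec["constant"]:
                rec["spearman_rho"], rec["spearman_p"] = 0.0, 1.0
            else:
                rho, p_s = stats.spearmanr(x, meta["grade"].to_numpy())
                rec["spearman_rho"], rec["spearman_p"] = float(rho), float(p_s)
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["q"] = bh_fdr(out["p"].to_numpy())
    if mode == "four_grade":
        out["spearman_q"] = bh_fdr(out["spearman_p"].to_numpy())
    out["significant"] = out["q"] < fdr_threshold
    return out
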