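"""Extra pathway variance explained by genus-pair interaction terms.

For a pathway Y and a co-abundant genus pair (x1, x2), a reduced model
Y = a + b1*x1 + b2*x2 + e is nested inside a full model with the product
term b12*x1*x2. The gain in explained variance dR^2 = R2_full - R2_reduced
is tested with the partial F statistic F = dR^2 * (n - 4) / (1 - R2_full)
on (1, n-4) degrees of freedom. Fits are computed within each hypertension
grade; the per-grade dR^2 values are then regressed on the numeric grade to
ask whether the interaction's functional contribution tracks severity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ValidationError
from .meta import bh_fdr


@dataclass
class InteractionFit:
    """Nested-regression result for one pathway x genus-pair x grade cell."""

    n: int
    alpha: float
    beta1: float
    beta2: float
    beta12: float
    resid_var: float
    r2_reduced: float
    r2_full: float
    delta_r2: float
    F: float
    p: float


def _ols_r2(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, resid, r2


def fit_interaction(Y, x1, x2) -> InteractionFit:
    """Fit reduced and full models and test the interaction term.

    Inputs are expected on the transformed scale (inverse-rank, covariate-
    residualized). Requires n >= 10 and a non-collinear genus pair
    (|r| <= 0.999).
    """
    y = np.asarray(Y, dtype=float)
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    n = y.size
    if a.size != n or b.size != n:
        raise ValidationError("Y, x1, x2 must have equal length")
    if n < 10:
        raise ValidationError("interaction fit needs n >= 10")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("constant predictor")
    if abs(np.corrcoef(a, b)[0, 1]) > 0.999:
        raise ValidationError("collinear genus pair (|r| > 0.999)")
    ones = np.ones(n)
    X_red = np.column_stack([ones, a, b])
    X_full = np.column_stack([ones, a, b, a * b])
    _, _, r2_red = _ols_r2(X_red, y)
    beta, resid, r2_full = _ols_r2(X_full, y)
    delta = max(r2_full - r2_red, 0.0)
    dof = n - 4
    F = delta * dof / (1.0 - r2_full) if r2_full < 1.0 else np.inf
    p = float(stats.f.sf(F, 1, dof))
    return InteractionFit(
        n=n,
        alpha=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        beta12=float(beta[3]),
        resid_var=float((resid**2).sum() / dof),
        r2_reduced=r2_red,
        r2_full=r2_full,
        delta_r2=delta,
        F=float(F),
        p=p,
    )


def fit_interactions_by_grade(
    pathways: pd.DataFrame,
    genera: pd.DataFrame,
    metadata: pd.DataFrame,
    pairs,
    pathway_ids=None,
    grades=(0, 1, 2, 3),
    min_n: int = 10,
) -> pd.DataFrame:
    """All pathway x pair x grade interaction fits, BH-corrected jointly.

    ``pathways`` and ``genera`` are transformed feature tables sharing the
    sample index with ``metadata``. Cells with fewer than ``min_n`` samples
    or a collinear pair are skipped. The FDR family is every fit of this
    call, the conservative joint reading.
    """
    meta = metadata.loc[pathways.index]
    if pathway_ids is None:
        pathway_ids = list(pathways.columns)
    records = []
    for grade in grades:
        mask = (meta["grade"] == grade).to_numpy()
        if mask.sum() < min_n:
            continue
        for gi, gj in pairs:
            if gi not in genera.columns or gj not in genera.columns:
                continue
            x1 = genera.loc[mask, gi].to_numpy()
            x2 = genera.loc[mask, gj].to_numpy()
            for pw in pathway_ids:
                y = pathways.loc[mask, pw].to_numpy()
                try:
                    fit = fit_interaction(y, x1, x2)
                except ValidationError:
                    continue
                records.append(
                    {
                        "pathway": pw,
                        "genus_i": gi,
                        "genus_j": gj,
                        "grade": grade,
                        "n": fit.n,
                        "alpha": fit.alpha,
                        "beta1": fit.beta1,
                        "beta2": fit.beta2,
                        "beta12": fit.beta12,
                        "r2_reduced": fit.r2_reduced,
                        "r2_full": fit.r2_full,
                        "delta_r2": fit.delta_r2,
                        "F": fit.F,
                        "p": fit.p,
                    }
                )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def variance_trend(fits: pd.DataFrame, trend_p_threshold: float = 0.05) -> pd.DataFrame:
    """OLS trend of the per-grade extra variance dR^2 on the numeric grade.

    One row per (pathway, pair) with at least 3 valid grade fits: the slope,
    its t-test p (unweighted OLS on at most 4 points), and a significance
    flag at ``trend_p_threshold``.
    """
    records = []
    for (pw, gi, gj), grp in fits.groupby(["pathway", "genus_i", "genus_j"]):
        grp = grp.dropna(subset=["delta_r2"])
        if len(grp) < 3:
            continue
        x = grp["grade"].to_numpy(dtype=float)
        y = grp["delta_r2"].to_numpy(dtype=float)
        res = stats.linregress(x, y)
        records.append(
            {
                "pathway": pw,
                "genus_i": gi,
                "genus_j": gj,
                "n_grades": len(grp),
                "slope": float(res.slope),
                "p_trend": float(res.pvalue),
                "significant": bool(res.pvalue < trend_p_threshold),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["pathway", "genus_i", "genus_j", "n_grades", "slope", "p_trend",
                 "significant"],
    )


def pathway_screen(
    two_group: pd.DataFrame,
    four_grade: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> list:
    """Severity-responsive pathway funnel feeding the interaction fits.

    Keeps pathways that pass, in order: two-group q < threshold, four-grade
    Kruskal-Wallis q < threshold, and Spearman trend q < threshold.
    """
    if two_group.empty or four_grade.empty:
        return []
    tg = two_group.set_index("feature")
    fg = four_grade.set_index("feature")
    out = []
    for pw in tg.index:
        if pw not in fg.index:
            continue
        if (
            tg.loc[pw, "q"] < fdr_threshold
            and fg.loc[pw, "q"] < fdr_threshold
            and fg.loc[pw, "spearman_q"] < fdr_threshold
        ):
            out.append(pw)
    return out
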