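"""Recovery and calibration experiments on generator output.

These experiments quantify how well each stage of the pipeline recovers the
structure the synthetic-cohort generator plants: latent-correlation recovery
of the compositional estimator, sensitivity/specificity of the heterogeneity
based differential-edge test, agreement of the partial-correlation adjustment
with its closed-form oracle, null calibration of the interaction F-test, and
sign recovery of the severity trend in interaction extra-variance. They are
run by the test suite and the results-reproduction script at fixed, moderate
problem sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cclasso import fit_latent_correlation
from .data import transform_features
from .differential import differential_edges, partial_correlation_matrix
from .interaction import fit_interaction, fit_interactions_by_grade, variance_trend
from .meta import meta_network
from .pipeline import fit_stratum_edges
from .simulate import SimulationConfig, simulate_cohort


def cclasso_block_recovery(
    n: int = 500, p: int = 30, n_seeds: int = 5, lam: float = 0.01, seed: int = 0
) -> dict:
    """RMSE of estimated vs planted off-diagonal correlations.

    One positive (rho = 0.6) and one negative (rho = -0.6) planted block in
    an otherwise diagonal latent correlation; averaged over seeds.
    """
    rmses, min_eigs = [], []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            n_taxa=p,
            n_regions=1,
            samples_per_region_group=(n, 0),
            grade_proportions=(1.0, 0.0, 0.0, 0.0),
            base_blocks=((0, 3, 0.6), (3, 2, -0.6)),
            region_jitter_sd=0.0,
            seed=seed + s,
        )
        table, _, _, manifest = simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_latent_correlation(table, lam=lam)
        planted = np.array(manifest.correlations["r00|g0"])
        iu = np.triu_indices(p, k=1)
        rmses.append(float(np.sqrt(np.mean((model.rho[iu] - planted[iu]) ** 2))))
        min_eigs.append(float(np.linalg.eigvalsh(model.Sigma).min()))
    return {
        "rmse": float(np.mean(rmses)),
        "worst_rmse": float(np.max(rmses)),
        "min_eigenvalue": float(np.min(min_eigs)),
        "n": n,
    }


def differential_detection(
    seed: int = 0,
    n_per_group: int = 200,
    n_regions: int = 14,
    p: int = 30,
    n_planted: int = 10,
    delta_z: float = 0.8,
    lam: float = 0.01,
) -> dict:
    """Sensitivity and null flag rate of the differential-edge test.

    ``n_planted`` disjoint genus pairs get correlation 0 in the control
    group and tanh(delta_z) in the case group; all other pairs are null.
    The test universe is every pair, so the null flag rate is measured over
    p(p-1)/2 - n_planted edges.
    """
    rho_case = float(np.tanh(delta_z))
    planted_pairs = [(2 * k, 2 * k + 1) for k in range(n_planted)]
    cfg = SimulationConfig(
        n_taxa=p,
        n_regions=n_regions,
        samples_per_region_group=(n_per_group, n_per_group),
        base_blocks=(),
        differential_edges=tuple(
            (i, j, 0.0, rho_case, "increased") for i, j in planted_pairs
        ),
        region_jitter_sd=0.02,
        seed=seed,
    )
    table, metadata, _, _ = simulate_cohort(cfg)
    group_meta = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, flag in [("case", 1), ("control", 0)]:
            grp = metadata[metadata["hypertension"] == flag]
            strata = {
                str(r): fit_stratum_edges(table.subset_samples(ids), lam=lam)
                for r, ids in grp.groupby("region").groups.items()
            }
            group_meta[label] = meta_network(strata)
    diff = differential_edges(group_meta["case"], group_meta["control"],
                              universe="all")
    planted_keys = {
        (f"g{i:03d}", f"g{j:03d}") for i, j in planted_pairs
    }
    flagged = {
        (r.genus_i, r.genus_j)
        for r in diff[diff["heterogeneous"]].itertuples(index=False)
    }
    n_null = len(diff) - len(planted_keys)
    return {
        "sensitivity": len(flagged & planted_keys) / len(planted_keys),
        "null_flag_rate": len(flagged - planted_keys) / n_null,
        "n_tested": int(len(diff)),
        "n": n_per_group,
    }


def partial_correlation_oracle_error(n_matrices: int = 100, seed: int = 0) -> dict:
    """Worst absolute deviation from the Schur-complement closed form."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        p = int(rng.integers(3, 12))
        A = rng.standard_normal((p, p + 3))
        C = A @ A.T / (p + 3)
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
        pcor = partial_correlation_matrix(R)
        for i in range(p):
            for j in range(i + 1, p):
                idx = [k for k in range(p) if k not in (i, j)]
                R_ab = R[np.ix_([i, j], [i, j])]
                R_ac = R[np.ix_([i, j], idx)]
                R_cc = R[np.ix_(idx, idx)]
                S = R_ab - R_ac @ np.linalg.solve(R_cc, R_ac.T)
                oracle = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
                worst = max(worst, abs(pcor[i, j] - oracle))
    return {"max_abs_error": float(worst), "n": n_matrices}


def interaction_null_calibration(
    n_replicates: int = 500, n: int = 100, seed: int = 0
) -> dict:
    """KS test of F-test p-values against Uniform(0,1) under the null."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_replicates):
        x1, x2, y = rng.standard_normal((3, n))
        pvals.append(fit_interaction(y, x1, x2).p)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(np.mean(pvals)),
            "n": n_replicates}


def severity_slope_sign_recovery(
    n_replicates: int = 100, n_per_grade: int = 300, seed: int = 0
) -> dict:
    """Fraction of generator replicates recovering the planted positive
    gamma-slope (0.1 + 0.2*grade) in the interaction extra-variance trend.

    Each replicate draws a full cohort (counts, covariates, pathway), runs
    the standard transform, fits the nested interaction models per grade on
    the observed transformed abundances, and checks the sign of the
    dR^2-on-grade slope.
    """
    hits = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_taxa=10,
            n_regions=1,
            samples_per_region_group=(n_per_grade, 3 * n_per_grade),
            grade_proportions=(0.25, 0.25, 0.25, 0.25),
            base_blocks=(),
            pathway_effects=(("pw", 0, 1, 0.3, 0.3, 0.1, 0.2, 1.0),),
            n_null_pathways=0,
            seed=seed + rep,
        )
        table, metadata, pathways, _ = simulate_cohort(cfg)
        rel = pd.DataFrame(
            table.counts.to_numpy(float) / table.depths().to_numpy()[:, None],
            index=table.sample_ids,
            columns=table.genus_ids,
        )
        genera_t = transform_features(rel[["g000", "g001"]], metadata)
        pw_t = transform_features(pathways, metadata)
        fits = fit_interactions_by_grade(
            pw_t, genera_t, metadata, pairs=[("g000", "g001")]
        )
        trend = variance_trend(fits)
        if len(trend) and trend.loc[0, "slope"] > 0:
            hits += 1
    return {"sign_recovery_rate": hits / n_replicates, "n": n_per_grade}
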