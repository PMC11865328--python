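import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from coabnet import (
    differential_abundance,
    grade_heterogeneity,
    grade_networks,
    meta_network,
    severity_trend,
)
from coabnet.data import ValidationError
from coabnet.pipeline import fit_stratum_edges
from coabnet.simulate import SimulationConfig, simulate_cohort


class TestSeverityTrend:
    def test_collinear_points_exact_slope(self):
        slope, se, p = severity_trend([0.1, 0.2, 0.3, 0.4], [0.05] * 4)
        assert slope == pytest.approx(0.100, abs=1e-12)

    def test_equal_effects_zero_slope(self):
        slope, _, _ = severity_trend([0.25, 0.25, 0.25, 0.25], [0.1] * 4)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_grade_reversal_negates_slope(self):
        z = [0.05, 0.18, 0.22, 0.41]
        se = [0.05, 0.06, 0.08, 0.1]
        s_fwd, _, _ = severity_trend(z, se, grades=[0, 1, 2, 3])
        s_rev, _, _ = severity_trend(z, se, grades=[3, 2, 1, 0])
        assert s_rev == pytest.approx(-s_fwd)

    def test_equal_se_matches_plain_ols(self):
        from scipy import stats

        z = [0.12, 0.31, 0.18, 0.44]
        weighted = severity_trend(z, [0.07] * 4)
        ols = stats.linregress([0, 1, 2, 3], z)
        assert weighted[0] == pytest.approx(ols.slope)
        assert weighted[2] == pytest.approx(ols.pvalue)

    def test_two_points_rejected(self):
        with pytest.raises(ValidationError):
            severity_trend([0.1, 0.2], [0.1, 0.1])


def graded_cohort(seed, severity_edges=(), n_regions=2, per_grade=200, n_taxa=8,
                  base_blocks=((0, 2, 0.3),)):
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        n_regions=n_regions,
        samples_per_region_group=(per_grade, 3 * per_grade),
        grade_proportions=(0.25, 0.25, 0.25, 0.25),
        base_blocks=base_blocks,
        severity_edges=severity_edges,
        region_jitter_sd=0.01,
        seed=seed,
    )
    return simulate_cohort(cfg)


class TestGradeNetworks:
    def test_grade_independent_cohort_agrees_across_grades(self):
        table, metadata, _, _ = graded_cohort(0)
        nets = grade_networks(table, metadata, min_stratum_n=50)
        deltas = []
        for a, b in itertools.combinations(nets, 2):
            merged = nets[a].merge(
                nets[b], on=["genus_i", "genus_j"], suffixes=("_a", "_b")
            )
            deltas.extend(
                (merged["pooled_z_a"] - merged["pooled_z_b"]).abs().tolist()
            )
        assert np.median(deltas) < 0.1

    def test_planted_severity_edge_increases_with_grade(self):
        hits = 0
        for seed in range(10):
            table, metadata, _, _ = graded_cohort(
                100 + seed, severity_edges=((3, 4, 0.15),), per_grade=300,
            )
            nets = grade_networks(table, metadata, min_stratum_n=50)
            zs = [
                nets[g]
                .set_index(["genus_i", "genus_j"])
                .loc[("g003", "g004"), "pooled_z"]
                for g in (0, 1, 2, 3)
            ]
            if all(np.diff(zs) > 0):
                hits += 1
        assert hits >= 8

    def test_missing_grade_raises_naming_it(self):
        table, metadata, _, _ = graded_cohort(1, per_grade=100)
        metadata = metadata[metadata["grade"] != 3]
        table = table.subset_samples(metadata.index)
        with pytest.raises(ValidationError, match="grade 3"):
            grade_networks(table, metadata, min_stratum_n=50)

    def test_single_grade_reduces_to_meta_network(self):
        table, metadata, _, _ = graded_cohort(2, per_grade=120)
        g0 = metadata[metadata["grade"] == 0]
        sub = table.subset_samples(g0.index)
        nets = grade_networks(sub, g0, grades=(0,), min_stratum_n=50)
        strata = {
            str(r): fit_stratum_edges(sub.subset_samples(ids))
            for r, ids in g0.groupby("region").groups.items()
        }
        expected = meta_network(strata)
        pd.testing.assert_frame_equal(nets[0], expected)


class TestGradeHeterogeneity:
    def test_four_grade_df_is_three(self):
        from scipy import stats

        nets = {
            g: pd.DataFrame(
                {
                    "genus_i": ["a"],
                    "genus_j": ["b"],
                    "pooled_z": [0.1 * g],
                    "se": [0.05],
                }
            )
            for g in (0, 1, 2, 3)
        }
        out = grade_heterogeneity(nets)
        row = out.iloc[0]
        assert row["K_grades"] == 4
        assert row["p_het"] == pytest.approx(
            stats.chi2.sf(row["Q"], 3)
        )
        assert row["severity_associated"] in (True, False)

    def test_merging_two_grades_recovers_two_group_q(self):
        from coabnet import cochran_q_between

        z = {0: 0.1, 1: 0.1, 2: 0.5, 3: 0.5}
        se = 0.05
        nets = {
            g: pd.DataFrame(
                {"genus_i": ["a"], "genus_j": ["b"], "pooled_z": [z[g]],
                 "se": [se]}
            )
            for g in (0, 2)
        }
        out = grade_heterogeneity(nets)
        Q2, _, p2, _ = cochran_q_between([0.1, 0.5], [se, se])
        assert out.iloc[0]["Q"] == pytest.approx(Q2)


class TestDifferentialAbundance:
    @staticmethod
    def _metadata(n_per_group, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        grades = np.repeat([0, 1], n_per_group)
        return pd.DataFrame(
            {
                "grade": grades,
                "hypertension": (grades >= 1).astype(int),
                "region": "r0",
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_power_on_planted_group_shift(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            meta = self._metadata(500)
            x = rng.standard_normal(1000)
            x[meta["hypertension"] == 1] += 0.5
            feats = pd.DataFrame({"f": x}, index=meta.index)
            out = differential_abundance(feats, meta, "two_group")
            if out.loc[0, "q"] < 0.05:
                hits += 1
        assert hits >= 19

    def test_size_under_permuted_labels(self):
        rng = np.random.default_rng(42)
        meta = self._metadata(200)
        feats = pd.DataFrame(
            rng.standard_normal((400, 60)),
            index=meta.index,
            columns=[f"f{i}" for i in range(60)],
        )
        out = differential_abundance(feats, meta, "two_group")
        assert (out["p"] < 0.05).mean() <= 0.12

    def test_identical_groups_give_large_p(self):
        meta = self._metadata(50)
        block = np.random.default_rng(1).standard_normal(50)
        feats = pd.DataFrame(
            {"f": np.concatenate([block, block])}, index=meta.index
        )
        out = differential_abundance(feats, meta, "two_group")
        assert out.loc[0, "p"] > 0.9

    def test_constant_feature_flagged(self):
        meta = self._metadata(20)
        feats = pd.DataFrame({"f": np.ones(40)}, index=meta.index)
        out = differential_abundance(feats, meta, "two_group")
        assert out.loc[0, "p"] == 1.0 and bool(out.loc[0, "constant"])

    def test_wilcoxon_matches_exact_enumeration(self):
        # brute-force null distribution of the rank-sum statistic at n1=n2=4
        from itertools import combinations

        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x = rng.standard_normal(4)
        y = rng.standard_normal(4) + 1.0
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        observed_u = res.statistic
        count_as_extreme = 0
        total = 0
        for idx in combinations(range(8), 4):
            r1 = ranks[list(idx)].sum()
            u1 = r1 - 4 * 5 / 2
            u = min(u1, 16 - u1)
            if u <= min(observed_u, 16 - observed_u):
                count_as_extreme += 1
            total += 1
        assert res.pvalue == pytest.approx(count_as_extreme / total)

    def test_four_grade_mode_reports_spearman_trend(self):
        rng = np.random.default_rng(9)
        grades = np.repeat([0, 1, 2, 3], 100)
        meta = pd.DataFrame(
            {"grade": grades, "hypertension": (grades >= 1).astype(int)},
            index=[f"s{i}" for i in range(400)],
        )
        feats = pd.DataFrame(
            {
                "trending": grades * 0.4 + rng.standard_normal(400),
                "flat": rng.standard_normal(400),
            },
            index=meta.index,
        )
        out = differential_abundance(feats, meta, "four_grade").set_index("feature")
        assert out.loc["trending", "spearman_q"] < 0.05
        assert out.loc["trending", "spearman_rho"] > 0
        assert out.loc["flat", "p"] > 0.01
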