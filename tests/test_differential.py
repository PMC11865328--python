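import numpy as np
import pandas as pd
import pytest

from coabnet import (
    adjust_partial_correlation,
    classify_differential,
    cochran_q_between,
    compare_replication,
    differential_edges,
    meta_network,
    partial_correlation_matrix,
    pool_random_effects,
)
from coabnet.data import ValidationError
from coabnet.pipeline import fit_stratum_edges
from coabnet.simulate import SimulationConfig, simulate_cohort


def schur_partial(R, i, j):
    """Independent closed form: partial correlation of (i, j) given the rest
    via the Schur complement of the conditioning block."""
    idx = [k for k in range(R.shape[0]) if k not in (i, j)]
    R_ab = R[np.ix_([i, j], [i, j])]
    R_ac = R[np.ix_([i, j], idx)]
    R_cc = R[np.ix_(idx, idx)]
    S = R_ab - R_ac @ np.linalg.solve(R_cc, R_ac.T)
    return S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])


def random_pd_correlation(p, rng):
    A = rng.standard_normal((p, p + 3))
    C = A @ A.T / (p + 3)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


class TestCochranQ:
    def test_hand_algebra(self):
        Q, df, p, I2 = cochran_q_between([0.4, -0.4], [0.1, 0.1])
        assert Q == pytest.approx(32.0, abs=1e-12)
        assert df == 1
        assert I2 == pytest.approx(96.875, abs=1e-3)

    def test_identical_effects(self):
        Q, df, p, I2 = cochran_q_between([0.25, 0.25], [0.1, 0.2])
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert I2 == 0.0

    def test_sign_flip_invariance(self):
        a = cochran_q_between([0.3, 0.1, -0.2], [0.1, 0.05, 0.2])
        b = cochran_q_between([-0.3, -0.1, 0.2], [0.1, 0.05, 0.2])
        assert a == pytest.approx(b)

    def test_matches_pooling_internal_q(self):
        z = np.array([0.1, 0.5, 0.3])
        v = np.array([0.01, 0.02, 0.015])
        Q, *_ = cochran_q_between(z, np.sqrt(v))
        assert Q == pytest.approx(pool_random_effects(z, v).Q)

    def test_single_effect_rejected(self):
        with pytest.raises(ValidationError):
            cochran_q_between([0.3], [0.1])


class TestClassifyDifferential:
    @pytest.mark.parametrize(
        "zc,zn,expected",
        [
            (0.3, 0.1, "increased"),
            (0.1, 0.3, "decreased"),
            (0.2, -0.2, "reversed"),
            (-0.4, -0.1, "increased"),
        ],
    )
    def test_classes(self, zc, zn, expected):
        assert classify_differential(zc, zn, True, True) == expected


class TestDifferentialEdges:
    @staticmethod
    def _meta_frame(rows):
        return pd.DataFrame(
            rows,
            columns=["genus_i", "genus_j", "pooled_z", "se", "significant"],
        ).assign(p=0.01, q=0.01)

    def test_label_swap_invariance_of_heterogeneity_flag(self):
        a = self._meta_frame([("x", "y", 0.6, 0.05, True)])
        b = self._meta_frame([("x", "y", 0.1, 0.05, True)])
        d1 = differential_edges(a, b)
        d2 = differential_edges(b, a)
        assert d1.loc[0, "heterogeneous"] == d2.loc[0, "heterogeneous"]
        assert d1.loc[0, "Q"] == pytest.approx(d2.loc[0, "Q"])

    def test_universe_union_of_significant(self):
        a = self._meta_frame(
            [("x", "y", 0.6, 0.05, True), ("x", "z", 0.0, 0.05, False)]
        )
        b = self._meta_frame(
            [("x", "y", 0.1, 0.05, False), ("x", "z", 0.05, 0.05, False)]
        )
        d = differential_edges(a, b)
        assert len(d) == 1  # (x, z) significant in neither group
        d_all = differential_edges(a, b, universe="all")
        assert len(d_all) == 2

    def test_reversed_class_requires_sign_disagreement(self):
        a = self._meta_frame([("x", "y", 0.5, 0.04, True)])
        b = self._meta_frame([("x", "y", -0.5, 0.04, True)])
        d = differential_edges(a, b)
        assert d.loc[0, "class"] == "reversed"


class TestPartialCorrelation:
    def test_three_variable_hand_formula(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        pcor = partial_correlation_matrix(R)
        assert pcor[0, 1] == pytest.approx((0.5 - 0.25) / 0.75)

    def test_identity_gives_zero_partials(self):
        pcor = partial_correlation_matrix(np.eye(4))
        off = pcor[np.triu_indices(4, 1)]
        assert np.allclose(off, 0.0)

    def test_matches_schur_complement_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = int(rng.integers(3, 8))
            R = random_pd_correlation(p, rng)
            pcor = partial_correlation_matrix(R)
            for i in range(p):
                for j in range(i + 1, p):
                    assert pcor[i, j] == pytest.approx(
                        schur_partial(R, i, j), abs=1e-10
                    )

    def test_independent_covariates_leave_correlation_unchanged(self):
        rng = np.random.default_rng(1)
        n = 1000
        z = rng.standard_normal(n)
        x1 = z + rng.standard_normal(n)
        x2 = z + rng.standard_normal(n)
        covs = rng.standard_normal((n, 4))
        block = np.column_stack([x1, x2, covs])
        R = np.corrcoef(block, rowvar=False)
        marginal = R[0, 1]
        adjusted = partial_correlation_matrix(R)[0, 1]
        assert abs(adjusted - marginal) < 0.02


def two_group_cohort(seed, differential=((0, 1, 0.0, 0.6, "increased"),),
                     n=(150, 150), n_regions=4, n_taxa=8):
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        n_regions=n_regions,
        samples_per_region_group=n,
        base_blocks=(),
        differential_edges=differential,
        region_jitter_sd=0.01,
        seed=seed,
    )
    return simulate_cohort(cfg)


def pooled_by_group(table, metadata, lam=0.01):
    out = {}
    for label, flag in [("hyp", 1), ("nonhyp", 0)]:
        grp = metadata[metadata["hypertension"] == flag]
        strata = {
            str(r): fit_stratum_edges(table.subset_samples(ids), lam=lam)
            for r, ids in grp.groupby("region").groups.items()
        }
        out[label] = meta_network(strata)
    return out


class TestAdjustment:
    def test_independent_covariates_rarely_change_edges(self):
        from coabnet.data import transform_features

        # a 30-taxon panel keeps the compositional closure bias of the
        # Pearson-based partial-correlation route (~ -1/(p-1)) negligible
        # relative to the pooled standard errors, as in a genus-scale panel
        table, metadata, _, _ = two_group_cohort(
            7, n=(300, 500), n_regions=2, n_taxa=30
        )
        nets = pooled_by_group(table, metadata)
        diff = differential_edges(nets["hyp"], nets["nonhyp"], universe="all")
        rel = pd.DataFrame(
            table.counts.to_numpy(float) / table.depths().to_numpy()[:, None],
            index=table.sample_ids, columns=table.genus_ids,
        )
        feats = transform_features(rel, metadata)
        hyp = metadata[metadata["hypertension"] == 1]
        feats_by_stratum = {
            str(r): feats.loc[ids]
            for r, ids in hyp.groupby("region").groups.items()
        }
        adjusted = adjust_partial_correlation(diff, feats_by_stratum, metadata)
        adj_meta = meta_network(
            {s: g.drop(columns="stratum") for s, g in adjusted.groupby("stratum")}
        ).set_index(["genus_i", "genus_j"])
        changed = 0
        for row in diff.itertuples(index=False):
            arow = adj_meta.loc[(row.genus_i, row.genus_j)]
            _, _, p, _ = cochran_q_between(
                [row.z_case, arow["pooled_z"]], [row.se_case, arow["se"]]
            )
            changed += int(p < 0.05)
        assert changed / len(diff) <= 0.10


class TestReplication:
    def test_identical_replication_fully_consistent(self):
        table, metadata, _, _ = two_group_cohort(3)
        nets = pooled_by_group(table, metadata)
        hyp_strata = {
            str(r): fit_stratum_edges(
                table.subset_samples(ids)
            )
            for r, ids in metadata[metadata["hypertension"] == 1]
            .groupby("region")
            .groups.items()
        }
        rep = compare_replication(nets["hyp"], hyp_strata)
        assert len(rep) > 0
        assert rep["consistent"].all()

    def test_self_replication_mostly_consistent(self):
        table, metadata, _, _ = two_group_cohort(4, n=(150, 300))
        nets = pooled_by_group(table, metadata)
        table2, metadata2, _, _ = two_group_cohort(5, n=(150, 300))
        rep_strata = {
            f"rep_{r}": fit_stratum_edges(table2.subset_samples(ids))
            for r, ids in metadata2[metadata2["hypertension"] == 1]
            .groupby("region")
            .groups.items()
        }
        rep = compare_replication(nets["hyp"], rep_strata)
        planted = rep[
            (rep.genus_i == "g000") & (rep.genus_j == "g001")
        ]
        assert len(rep) > 0
        assert rep["consistent"].mean() >= 0.8
        if len(planted):
            assert planted["replicated"].all()

    def test_null_replication_rarely_consistent_for_planted_edge(self):
        table, metadata, _, _ = two_group_cohort(6, n=(150, 300))
        nets = pooled_by_group(table, metadata)
        # replication cohort with the planted correlation removed
        table0, metadata0, _, _ = two_group_cohort(
            8, differential=(), n=(150, 300)
        )
        rep_strata = {
            f"rep_{r}": fit_stratum_edges(table0.subset_samples(ids))
            for r, ids in metadata0[metadata0["hypertension"] == 1]
            .groupby("region")
            .groups.items()
        }
        rep = compare_replication(nets["hyp"], rep_strata).set_index(
            ["genus_i", "genus_j"]
        )
        assert not rep.loc[("g000", "g001"), "consistent"]
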