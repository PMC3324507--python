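import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import shscreen as sh
from shscreen.diffabund import (
    DesignMatrix,
    build_design,
    call_hits,
    cluster_hits,
    cross_line_specificity,
    estimate_variance_prior,
    fit_probe_model,
    moderate_variances,
    timecourse_drift_test,
    treated_vs_vehicle_matrix,
)
from shscreen.screenio import IntensityMatrix

from conftest import make_sheet


def matrix_from(data, samples):
    df = pd.DataFrame(np.asarray(data, dtype=float),
                      index=[f"P{i+1}" for i in range(np.shape(data)[0])],
                      columns=samples)
    return IntensityMatrix(df, scale="log2")


class TestBuildDesign:
    def test_full_factorial_has_rank_five(self, tiny_sheet):
        design = build_design(tiny_sheet)
        assert design.frame.shape == (18, 5)
        assert np.linalg.matrix_rank(design.frame.to_numpy()) == 5
        assert set(design.frame.columns) == {
            "intercept", "treated", "timepoint_T2", "replicate_2", "replicate_3"
        }

    def test_doses_pool_into_one_treated_level(self, small_screen):
        _, sheet, _, _ = small_screen
        design = build_design(sheet)
        post = sheet[~sheet["is_preselection"]].set_index("sample_id")
        treated = design.frame["treated"]
        assert ((post.loc[treated.index, "dose"] > 0) == (treated == 1.0)).all()

    def test_vehicle_only_sheet_is_rank_deficient(self):
        sheet = make_sheet(doses=(0.0,))
        with pytest.raises(sh.ValidationError, match="rank"):
            build_design(sheet)

    def test_single_replicate_drops_replicate_columns(self):
        sheet = make_sheet(replicates=(1,))
        design = build_design(sheet)
        assert not any(c.startswith("replicate") for c in design.frame.columns)

    def test_t0_samples_never_enter_design(self, tiny_sheet):
        design = build_design(tiny_sheet)
        t0 = set(tiny_sheet.loc[tiny_sheet["is_preselection"], "sample_id"])
        assert not t0 & set(design.sample_ids)


class TestFitProbeModel:
    def test_noise_free_shift_recovered_exactly(self, tiny_sheet):
        design = build_design(tiny_sheet)
        frame = design.frame
        # values fully explained by the model: baseline + time + replicate
        # effects, with treated samples exactly 1.0 below vehicle
        y = (
            2.0
            - 1.0 * frame["treated"]
            + 0.3 * frame["timepoint_T2"]
            + 0.1 * frame["replicate_2"]
            + 0.2 * frame["replicate_3"]
        )
        mat = matrix_from(y.to_numpy()[None, :], list(design.sample_ids))
        fits = fit_probe_model(mat, design)
        assert fits["log2fc"].iloc[0] == pytest.approx(-1.0, abs=1e-12)
        assert fits["sigma2"].iloc[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n, extra = 18, rng.integers(1, 4)
            X = np.column_stack(
                [np.ones(n), rng.integers(0, 2, n).astype(float)]
                + [rng.normal(size=n) for _ in range(extra)]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            y = rng.normal(size=n)
            cols = ["intercept", "treated"] + [f"x{k}" for k in range(extra)]
            design = DesignMatrix(
                pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)])
            )
            mat = matrix_from(y[None, :], list(design.frame.index))
            fit = fit_probe_model(mat, design).iloc[0]
            # independent oracle: SVD least squares + explicit formulas
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            df = n - X.shape[1]
            s2 = resid @ resid / df
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), df)
            assert fit["log2fc"] == pytest.approx(beta[1], abs=1e-8)
            assert fit["se"] == pytest.approx(se, abs=1e-8)
            assert fit["p"] == pytest.approx(p, abs=1e-8)

    def test_saturated_design_flags_unfit(self):
        n = 3
        design = DesignMatrix(
            pd.DataFrame(
                np.column_stack([np.ones(n), [0, 1, 0], [0, 0, 1]]),
                columns=["intercept", "treated", "x"],
                index=[f"s{i}" for i in range(n)],
            )
        )
        mat = matrix_from(np.random.default_rng(0).normal(size=(2, n)),
                          list(design.frame.index))
        fits = fit_probe_model(mat, design)
        assert not fits["ok"].any()
        assert fits["p"].isna().all()


class TestModeration:
    def test_d0_zero_reproduces_ordinary_statistics(self, small_screen):
        matrix, sheet, annotation, _ = small_screen
        detected, _ = sh.run_preprocess(matrix, annotation, sheet)
        fits = fit_probe_model(detected, build_design(sheet))
        mod = moderate_variances(fits, d0=0.0, s0sq=1.0)
        np.testing.assert_allclose(mod["t_moderated"], mod["t"], rtol=1e-12)
        np.testing.assert_allclose(mod["p_moderated"], mod["p"], rtol=1e-12)

    def test_equal_variances_are_a_fixed_point(self):
        # identical sample variances: the prior collapses onto them and the
        # moderated statistic equals the ordinary one
        rng = np.random.default_rng(5)
        n, d = 200, 10
        beta = rng.normal(size=n)
        fits = pd.DataFrame(
            {
                "log2fc": beta,
                "se": 0.5,
                "df_resid": d,
                "t": beta / 0.5,
                "p": 2 * stats.t.sf(np.abs(beta / 0.5), d),
                "sigma2": 0.25,
                "v_treatment": 1.0,
                "ok": True,
            },
            index=[f"P{i}" for i in range(n)],
        )
        mod = moderate_variances(fits)
        assert np.isinf(mod["d0"].iloc[0])
        assert mod["s0sq"].iloc[0] == pytest.approx(0.25)
        np.testing.assert_allclose(mod["t_moderated"], mod["t"], rtol=1e-12)

    def test_hyperparameter_recovery(self):
        # scaled-F simulation with known prior (d0=4, s0^2=0.25)
        d0_true, s0_true, d, n = 4.0, 0.25, 10, 1000
        d0s, s0s = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sigma2 = d0_true * s0_true / rng.chisquare(d0_true, n)
            s2 = sigma2 * rng.chisquare(d, n) / d
            d0, s0 = estimate_variance_prior(s2, np.full(n, float(d)))
            d0s.append(d0)
            s0s.append(s0)
        assert abs(np.mean(d0s) - d0_true) / d0_true < 0.25
        assert abs(np.mean(s0s) - s0_true) / s0_true < 0.10

    def test_all_zero_variances_error(self):
        fits = pd.DataFrame(
            {"log2fc": [1.0, 2.0], "se": 0.0, "df_resid": 5, "t": 0.0, "p": 1.0,
             "sigma2": 0.0, "v_treatment": 1.0, "ok": True},
            index=["P1", "P2"],
        )
        with pytest.raises(sh.ValidationError):
            moderate_variances(fits)


class TestCallHits:
    def make_fits(self, rows):
        return pd.DataFrame(
            [{"log2fc": fc, "p": p} for fc, p in rows],
            index=[f"P{i+1}" for i in range(len(rows))],
        )

    def test_reference_depleted_probe_is_a_hit(self):
        hits = call_hits(self.make_fits([(-1.197, 0.0003)]), direction="depleted")
        assert len(hits.probe_hits) == 1
        assert hits.probe_hits["direction"].iloc[0] == "depleted"

    def test_boundaries_inclusive(self):
        hits = call_hits(self.make_fits([(-0.58, 0.01)]))
        assert len(hits.probe_hits) == 1

    def test_p_failure_excludes(self):
        hits = call_hits(self.make_fits([(-0.594, 0.02)]))
        assert len(hits.probe_hits) == 0

    def test_direction_split(self):
        fits = self.make_fits([(-0.7, 0.001), (0.7, 0.001), (-0.1, 0.001)])
        both = call_hits(fits, direction="both")
        dep = call_hits(fits, direction="depleted")
        enr = call_hits(fits, direction="enriched")
        assert set(both.probe_hits["probe_id"]) == {"P1", "P2"}
        assert set(dep.probe_hits["probe_id"]) == {"P1"}
        assert set(enr.probe_hits["probe_id"]) == {"P2"}

    @given(
        fc_relax=st.floats(0, 0.5),
        p_relax=st.floats(0, 0.5),
        seed=st.integers(0, 100),
    )
    def test_relaxing_thresholds_is_monotone(self, fc_relax, p_relax, seed):
        rng = np.random.default_rng(seed)
        fits = pd.DataFrame(
            {"log2fc": rng.normal(0, 1, 50), "p": rng.uniform(0, 0.05, 50)},
            index=[f"P{i}" for i in range(50)],
        )
        strict = call_hits(fits, fc_cut=0.58, p_cut=0.01)
        loose = call_hits(fits, fc_cut=0.58 - fc_relax, p_cut=0.01 + p_relax)
        assert set(strict.probe_hits["probe_id"]) <= set(loose.probe_hits["probe_id"])


class TestGeneAggregation:
    def test_fixture_counts(self):
        fixture = sh.make_reference_hit_fixture().set_index("probe_id")
        hits = call_hits(fixture, direction="depleted")
        summary = sh.aggregate_genes(hits)
        assert summary.set_index("target_gene").loc["TTK", "probes_scored"] == 3
        assert summary["probes_scored"].sum() == 23
        assert len(summary) == 15

    def test_empty_hits_empty_summary(self):
        fits = pd.DataFrame({"log2fc": [0.0], "p": [1.0]}, index=["P1"])
        assert sh.aggregate_genes(call_hits(fits)).empty

    def test_two_probes_one_gene(self, tiny_annotation):
        fits = pd.DataFrame({"log2fc": [-1.0, -1.0], "p": [0.001, 0.001]},
                            index=["P1", "P2"])
        hits = call_hits(fits, tiny_annotation)
        summary = sh.aggregate_genes(hits)
        assert summary.set_index("target_gene").loc["GA", "probes_scored"] == 2

    def test_unmapped_probe_warned_and_excluded(self):
        fits = pd.DataFrame({"log2fc": [-1.0], "p": [0.001]}, index=["PX"])
        hits = call_hits(fits)
        with pytest.warns(UserWarning, match="PX"):
            summary = sh.aggregate_genes(hits)
        assert summary.empty


class TestCrossLineSpecificity:
    def _hits(self, rows, universe=("P1", "P2", "P3")):
        fits = pd.DataFrame(
            [{"log2fc": fc, "p": p} for _, fc, p in rows],
            index=[pid for pid, _, _ in rows],
        ).reindex(list(universe), fill_value=1.0)
        fits["log2fc"] = [dict((pid, fc) for pid, fc, _ in rows).get(u, 0.0)
                          for u in universe]
        fits["p"] = [dict((pid, p) for pid, _, p in rows).get(u, 1.0)
                     for u in universe]
        return call_hits(fits)

    def test_disjoint_hit_sets_unchanged(self):
        primary = self._hits([("P1", -1.0, 0.001)])
        control = self._hits([("P2", -1.0, 0.001)])
        unique, flagged = cross_line_specificity(primary, control)
        assert set(unique.probe_hits["probe_id"]) == {"P1"}
        assert flagged.empty

    def test_shared_same_direction_removed(self):
        primary = self._hits([("P1", -1.0, 0.001), ("P2", -1.0, 0.001)])
        control = self._hits([("P1", -1.0, 0.001)])
        unique, flagged = cross_line_specificity(primary, control)
        assert set(unique.probe_hits["probe_id"]) == {"P2"}
        assert set(flagged["probe_id"]) == {"P1"}

    def test_opposite_direction_retained(self):
        primary = self._hits([("P1", -1.0, 0.001)])
        control = self._hits([("P1", 1.0, 0.001)])
        unique, flagged = cross_line_specificity(primary, control)
        assert set(unique.probe_hits["probe_id"]) == {"P1"}
        assert flagged.empty

    def test_mismatched_universe_errors(self):
        primary = self._hits([("P1", -1.0, 0.001)])
        control = self._hits([("P1", -1.0, 0.001)], universe=("P1", "P2"))
        with pytest.raises(sh.ValidationError, match="universe"):
            cross_line_specificity(primary, control)


class TestDriftTest:
    def _vehicle_sheet(self, replicates):
        return make_sheet(doses=(0.0,), replicates=tuple(range(1, replicates + 1)))

    def test_planted_shift_reaches_minimum_p(self):
        sheet = self._vehicle_sheet(3)
        veh = sheet[~sheet["is_preselection"]]
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.1, size=(1, len(veh)))
        y[0, (veh["timepoint"] == "T2").to_numpy()] += 2.0
        mat = matrix_from(y, veh["sample_id"].tolist())
        res = timecourse_drift_test(mat, sheet, n_perm=200, seed=1)
        assert res["p"].iloc[0] == pytest.approx(1 / 201)

    def test_constant_probe_has_zero_f(self):
        sheet = self._vehicle_sheet(3)
        veh = sheet[~sheet["is_preselection"]]
        mat = matrix_from(np.full((1, len(veh)), 3.0), veh["sample_id"].tolist())
        res = timecourse_drift_test(mat, sheet, n_perm=50, seed=0)
        assert res["F"].iloc[0] == 0.0

    def test_null_p_values_approximately_uniform(self):
        # 5 replicates give 31 distinct non-identity shuffles, enough for a
        # smooth permutation distribution
        sheet = self._vehicle_sheet(5)
        veh = sheet[~sheet["is_preselection"]]
        rng = np.random.default_rng(3)
        mat = matrix_from(rng.normal(size=(300, len(veh))), veh["sample_id"].tolist())
        res = timecourse_drift_test(mat, sheet, n_perm=199, seed=4)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_single_timepoint_errors(self):
        sheet = make_sheet(doses=(0.0,), timepoints=("T0", "T1"))
        veh = sheet[~sheet["is_preselection"]]
        mat = matrix_from(np.zeros((1, len(veh))), veh["sample_id"].tolist())
        with pytest.raises(sh.ValidationError, match="timepoint"):
            timecourse_drift_test(mat, sheet)


class TestClustering:
    def test_identical_rows_merge_at_distance_zero(self):
        hm = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]],
                          index=["a", "b", "c"], columns=["s1", "s2"])
        out = cluster_hits(hm)
        first_merge = out["row_linkage"][0]
        assert first_merge[2] == 0.0
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_planted_blocks_recovered_at_top_split(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(7)
        depleted = rng.normal(-1.0, 0.1, size=(10, 6))
        enriched = rng.normal(1.0, 0.1, size=(10, 6))
        hm = pd.DataFrame(np.vstack([depleted, enriched]),
                          index=[f"d{i}" for i in range(10)] + [f"e{i}" for i in range(10)])
        out = cluster_hits(hm)
        groups = fcluster(out["row_linkage"], 2, criterion="maxclust")
        assert len(set(groups[:10])) == 1
        assert len(set(groups[10:])) == 1
        assert groups[0] != groups[-1]

    def test_rerun_is_deterministic(self, small_screen):
        matrix, sheet, annotation, _ = small_screen
        detected, _ = sh.run_preprocess(matrix, annotation, sheet)
        hm = treated_vs_vehicle_matrix(detected, sheet).iloc[:40]
        out1 = cluster_hits(hm)
        out2 = cluster_hits(hm)
        assert out1["row_order"] == out2["row_order"]
        assert out1["col_order"] == out2["col_order"]

    def test_single_row_trivial_ordering(self):
        hm = pd.DataFrame([[1.0, 2.0]], index=["only"], columns=["s1", "s2"])
        out = cluster_hits(hm)
        assert out["row_order"] == ["only"]
        assert out["row_linkage"] is None
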