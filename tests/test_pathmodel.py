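"""Standardized path models: normal equations, elimination, decomposition."""

import re

import numpy as np
import pandas as pd
import pytest

import kpath
from kpath.pathmodel import (
    STUDY_PREDICTORS,
    CollinearityError,
    compare_with_published,
    fit_path_model,
)
from tests.conftest import random_regression_frame


def zmat_of(df, cols):
    return kpath.zscore(df, cols)


class TestFitStandardized:
    def test_single_predictor_equals_simple_correlation(self, rng):
        df, cols = random_regression_frame(rng, n=50, p=3)
        z = zmat_of(df, ["y", "x0"])
        direct, r2, _ = kpath.fit_standardized(z, "y", ["x0"])
        r = np.corrcoef(df["y"], df["x0"])[0, 1]
        assert direct["x0"] == pytest.approx(r, abs=1e-12)
        assert r2 == pytest.approx(r * r, abs=1e-12)

    def test_two_predictor_closed_form(self):
        # r_y1=0.7, r_y2=0.6, r_12=0.5 -> P1=(0.7-0.5*0.6)/0.75, P2=(0.6-0.5*0.7)/0.75
        # construct data with exactly these sample correlations via
        # Cholesky on the target matrix applied to orthonormalized noise
        target = np.array([[1.0, 0.5, 0.7], [0.5, 1.0, 0.6], [0.7, 0.6, 1.0]])
        rng = np.random.default_rng(42)
        n = 200
        raw = rng.standard_normal((n, 3))
        raw -= raw.mean(axis=0)
        # orthonormalize columns then impose the exact target correlation
        q, _ = np.linalg.qr(raw)
        X = q @ np.linalg.cholesky(target).T
        df = pd.DataFrame(X, columns=["x1", "x2", "y"])
        z = zmat_of(df, ["y", "x1", "x2"])
        direct, r2, _ = kpath.fit_standardized(z, "y", ["x1", "x2"])
        assert direct["x1"] == pytest.approx((0.7 - 0.5 * 0.6) / 0.75, abs=1e-9)
        assert direct["x2"] == pytest.approx((0.6 - 0.5 * 0.7) / 0.75, abs=1e-9)
        assert r2 == pytest.approx(0.7 * direct["x1"] + 0.6 * direct["x2"], abs=1e-9)

    def test_duplicated_predictor_collinearity_error(self, rng):
        df, cols = random_regression_frame(rng, n=30, p=3)
        df["x0_copy"] = df["x0"]
        z = zmat_of(df, ["y", "x0", "x0_copy", "x1"])
        with pytest.raises(CollinearityError, match="x0"):
            kpath.fit_standardized(z, "y", ["x0", "x0_copy", "x1"])

    def test_oracle_equivalence_raw_least_squares(self, rng):
        """Normal-equations coefficients == brute-force OLS on raw data,
        standardized after the fit, on 100 random instances."""
        for i in range(100):
            r = np.random.default_rng(1000 + i)
            df, cols = random_regression_frame(r, n=30, p=3)
            z = zmat_of(df, ["y", *cols])
            direct, _, _ = kpath.fit_standardized(z, "y", cols)
            X = np.column_stack([np.ones(len(df)), df[cols].to_numpy()])
            b, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
            sy = df["y"].std(ddof=1)
            for j, c in enumerate(cols):
                b_std = b[j + 1] * df[c].std(ddof=1) / sy
                assert direct[c] == pytest.approx(b_std, abs=1e-8)

    def test_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        df, cols = random_regression_frame(rng, n=40, p=4)
        z = zmat_of(df, ["y", *cols])
        direct, r2, pvals = kpath.fit_standardized(z, "y", cols)
        zf = z.to_frame()
        fit = sm.OLS(zf["y"], sm.add_constant(zf[cols])).fit()
        for c in cols:
            assert direct[c] == pytest.approx(fit.params[c], abs=1e-10)
            assert pvals[c] == pytest.approx(fit.pvalues[c], abs=1e-10)
        assert r2 == pytest.approx(fit.rsquared, abs=1e-10)

    def test_permutation_invariance(self, rng):
        df, cols = random_regression_frame(rng, n=40, p=4)
        z = zmat_of(df, ["y", *cols])
        d1, _, _ = kpath.fit_standardized(z, "y", cols)
        d2, _, _ = kpath.fit_standardized(z, "y", cols[::-1])
        for c in cols:
            assert abs(d1[c] - d2[c]) < 1e-12

    def test_too_many_predictors_refused(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 5)),
                          columns=["y", "a", "b", "c", "d"])
        z = zmat_of(df, list(df.columns))
        with pytest.raises(ValueError, match="df"):
            kpath.fit_standardized(z, "y", ["a", "b", "c", "d"])


class TestBackwardElimination:
    def test_pure_noise_predictor_removed(self):
        rng = np.random.default_rng(2024)
        n = 200
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)  # pure noise
        y = 0.8 * x1 + rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        z = zmat_of(df, ["y", "x1", "x2"])
        retained, trace = kpath.backward_eliminate(z, "y", ["x1", "x2"])
        assert retained == ["x1"]
        assert trace[0][0] == "x2" and trace[0][1] > 0.05
        # full-enumeration check: of all subsets, {x1} is the one whose
        # members are all individually significant
        for subset in [["x1"], ["x2"], ["x1", "x2"]]:
            _, _, p = kpath.fit_standardized(z, "y", subset)
            if subset == ["x1"]:
                assert all(v <= 0.05 for v in p.values())

    def test_alpha_one_keeps_full_model(self, rng):
        df, cols = random_regression_frame(rng, n=40, p=4)
        z = zmat_of(df, ["y", *cols])
        retained, trace = kpath.backward_eliminate(z, "y", cols, alpha_remove=1.0)
        assert retained == cols and trace == []

    def test_all_significant_keeps_everything(self):
        rng = np.random.default_rng(77)
        n = 300
        x1, x2 = rng.standard_normal((2, n))
        y = 0.7 * x1 - 0.7 * x2 + 0.3 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        z = zmat_of(df, ["y", "x1", "x2"])
        retained, trace = kpath.backward_eliminate(z, "y", ["x1", "x2"])
        assert set(retained) == {"x1", "x2"} and trace == []

    def test_everything_eliminated_warns_and_residue_is_one(self):
        rng = np.random.default_rng(88)
        df = pd.DataFrame(rng.standard_normal((60, 3)), columns=["y", "x1", "x2"])
        z = zmat_of(df, ["y", "x1", "x2"])
        with pytest.warns(UserWarning, match="eliminated"):
            retained, trace = kpath.backward_eliminate(z, "y", ["x1", "x2"], alpha_remove=1e-12)
        assert retained == []
        result = kpath.decompose(z, "y", retained, eliminated=trace)
        assert result.residue == 1.0 and result.r2 == 0.0


class TestDecomposition:
    def test_single_predictor_no_indirect(self, rng):
        df, cols = random_regression_frame(rng, n=50, p=2)
        z = zmat_of(df, ["y", "x0"])
        res = kpath.decompose(z, "y", ["x0"])
        assert res.indirect_total["x0"] == 0.0
        assert res.total["x0"] == pytest.approx(res.simple_r["x0"], abs=1e-12)

    def test_two_predictor_hand_computation(self):
        # same construction as the closed-form fit test: indirect on x1 is
        # r_12 * P2 = 0.5 * (1/3) = 1/6, total = 8/15 + 1/6 = 0.7 = r_y1
        target = np.array([[1.0, 0.5, 0.7], [0.5, 1.0, 0.6], [0.7, 0.6, 1.0]])
        rng = np.random.default_rng(42)
        raw = rng.standard_normal((200, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        X = q @ np.linalg.cholesky(target).T
        df = pd.DataFrame(X, columns=["x1", "x2", "y"])
        z = zmat_of(df, ["y", "x1", "x2"])
        res = kpath.decompose(z, "y", ["x1", "x2"])
        assert res.indirect_total["x1"] == pytest.approx(0.5 * (1.0 / 3.0), abs=1e-9)
        assert res.total["x1"] == pytest.approx(0.7, abs=1e-9)

    def test_total_effect_identity_random_instances(self):
        """Eq.-style identity: with all predictors retained,
        direct + sum(indirect) == simple r, to 1e-8, on 100 instances."""
        for i in range(100):
            rng = np.random.default_rng(5000 + i)
            df, cols = random_regression_frame(rng, n=25, p=4)
            z = zmat_of(df, ["y", *cols])
            res = kpath.decompose(z, "y", cols)
            for c in cols:
                assert res.total[c] == pytest.approx(res.simple_r[c], abs=1e-8)

    def test_residue_squared_plus_r2_is_one(self, rng):
        df, cols = random_regression_frame(rng, n=40, p=3)
        z = zmat_of(df, ["y", *cols])
        res = kpath.decompose(z, "y", cols)
        assert res.residue**2 + res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.residue == pytest.approx(np.sqrt(1 - res.r2), abs=1e-12)


@pytest.fixture(scope="module")
def models():
    with pytest.warns(UserWarning, match="degrees of freedom"):
        return kpath.run_study_models()


class TestPaperModels:
    def test_three_responses_with_bounded_predictor_sets(self, models):
        assert set(models) == {"wsK", "neK", "eK"}
        for resp, res in models.items():
            assert len(res.predictors) <= 8
            assert res.predictors == STUDY_PREDICTORS[resp]

    def test_decomposition_identity_on_study_data(self, models):
        for res in models.values():
            for p in res.predictors:
                assert res.total[p] == pytest.approx(res.simple_r[p], abs=1e-8)

    def test_published_simple_correlations_recovered(self, models, zmat):
        """The published tables' first column equals the simple
        correlations; the recomputed ones should agree closely for the
        potassium-form block."""
        report = compare_with_published(models["neK"], zmat)
        for var, printed in [("eK", 0.98), ("wsK", 0.77), ("SOM", 0.8), ("S", -0.86)]:
            assert report.loc[var, "computed_simple_r"] == pytest.approx(printed, abs=0.015)

    def test_ek_direct_coefficient_of_nek_matches_quoted_value(self, models):
        # the text quotes 1.10 for the neK -> eK path contribution
        assert models["eK"].direct["neK"] == pytest.approx(1.10, abs=0.01)

    def test_parameter_recovery_on_synthetic_structural_data(self):
        from kpath.synthetic import SyntheticSpec, generate

        beta = {"x1": 0.5, "x2": -0.3, "x3": 0.2}
        target = np.eye(3)
        maes = []
        for n in (100, 1000, 10000):
            errs = []
            for seed in range(5):
                spec = SyntheticSpec(
                    n=n, variables=["x1", "x2", "x3"], target_corr=target,
                    structural={"y": beta}, seed=seed,
                )
                df, truth = generate(spec)
                z = zmat_of(df, ["y", "x1", "x2", "x3"])
                direct, _, _ = kpath.fit_standardized(z, "y", ["x1", "x2", "x3"])
                errs.append(np.mean([abs(direct[k] - beta[k]) for k in beta]))
            maes.append(np.mean(errs))
        assert maes[2] < maes[0]  # error shrinks with n
        assert maes[2] < 0.05


class TestDotExport:
    def parse_dot(self, text):
        nodes = {m.strip() for m in re.findall(r'^\s*"?([\w/\. ]+?)"?\s*\[', text, re.M)}
        edges = [
            (a.strip(), b.strip())
            for a, b in re.findall(r'"?([\w/\. ]+?)"?\s*->\s*"?([\w/\. ]+?)"?\s*\[', text)
        ]
        return nodes, edges

    def test_single_predictor_three_nodes_two_edges(self, tmp_path, rng):
        df, cols = random_regression_frame(rng, n=30, p=2)
        z = zmat_of(df, ["y", "x0"])
        res = kpath.decompose(z, "y", ["x0"])
        text = kpath.export_path_diagram(res, tmp_path / "d.dot")
        nodes, edges = self.parse_dot(text)
        assert nodes == {"y", "x0", "e"}
        assert len(edges) == 2

    def test_empty_retained_set_response_and_residue_only(self, tmp_path, rng):
        df, cols = random_regression_frame(rng, n=30, p=2)
        z = zmat_of(df, ["y", "x0"])
        res = kpath.decompose(z, "y", [])
        text = kpath.export_path_diagram(res, tmp_path / "d.dot")
        nodes, edges = self.parse_dot(text)
        assert nodes == {"y", "e"}
        assert edges == [("e", "y")]

    def test_study_wsk_model_diagram_well_formed(self, tmp_path, zmat):
        with pytest.warns(UserWarning):
            res = fit_path_model(zmat, "wsK", STUDY_PREDICTORS["wsK"])
        text = kpath.export_path_diagram(res, tmp_path / "wsk.dot", z=zmat)
        assert text.startswith("digraph") and text.rstrip().endswith("}")
        nodes, edges = self.parse_dot(text)
        # all 8 predictors feed the response; neK-eK (r=0.98) gets a
        # double-headed edge
        assert sum(1 for a, b in edges if b == "wsK") == 9  # 8 predictors + e
        assert ("neK", "eK") in edges or ("eK", "neK") in edges
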