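import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as hs
from scipy import optimize, stats

import stratomics as st
from stratomics.stratified_association import AssociationResult


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

class TestSplitCohort:
    def make_meta(self, n_ad, n_co, stratum="33"):
        n = n_ad + n_co
        meta = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": ["AD"] * n_ad + ["CO"] * n_co,
            "age": 70.0, "sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "stratum": stratum, "batch": "b1",
        })
        return meta.set_index("sample_id", drop=False)

    def test_balanced_split(self):
        meta = self.make_meta(10, 10)
        split = st.split_cohort(meta, seed=0)
        for status in ("AD", "CO"):
            sub = split[meta["status"] == status]
            assert (sub == "discovery").sum() == 5
            assert (sub == "replication").sum() == 5

    def test_odd_count_plus_minus_one(self):
        meta = self.make_meta(11, 10)
        split = st.split_cohort(meta, seed=0)
        ad = split[meta["status"] == "AD"]
        assert sorted([(ad == "discovery").sum(),
                       (ad == "replication").sum()]) == [5, 6]

    def test_deterministic(self):
        meta = self.make_meta(20, 30)
        a = st.split_cohort(meta, seed=5)
        b = st.split_cohort(meta, seed=5)
        pd.testing.assert_series_equal(a, b)
        assert not a.equals(st.split_cohort(meta, seed=6))

    def test_small_stratum_excluded_with_warning(self, caplog):
        meta = pd.concat([self.make_meta(10, 10, "33")])
        tiny = self.make_meta(1, 5, "44")
        tiny.index = tiny["sample_id"] = [f"T{i}" for i in range(6)]
        meta = pd.concat([meta, tiny])
        with caplog.at_level("WARNING"):
            split = st.split_cohort(meta, seed=1)
        assert split[meta["stratum"] == "44"].isna().all()
        assert "excluded" in caplog.text


# ----------------------------------------------------------------------
# per-analyte fits
# ----------------------------------------------------------------------

def logit_nll(params, y, X):
    eta = X @ params
    return np.sum(np.log1p(np.exp(eta))) - y @ eta


class TestFitAssociation:
    def test_symmetric_null_gives_zero_beta(self):
        meta = pd.DataFrame({
            "sample_id": list("abcd"), "status": ["CO", "CO", "AD", "AD"],
            "age": [70.0] * 4, "sex": ["M"] * 4, "stratum": "33",
            "batch": "b1"}).set_index("sample_id", drop=False)
        values = pd.Series([-1.0, 1.0, -1.0, 1.0], index=meta.index)
        # drop covariates from the design by making them constant; the
        # analyte is orthogonal to status so its MLE is 0 — but n < 10
        res = st.fit_association(values, meta)
        assert not res.converged and "usable samples" in res.reason

    def test_beta_matches_independent_ml_oracle(self):
        """Logistic beta for the analyte term matches a direct numerical
        maximum-likelihood oracle (hand-written NLL + scipy optimizer)."""
        rng = np.random.default_rng(0)
        n = 60
        meta = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": ["AD"] * 30 + ["CO"] * 30,
            "age": rng.normal(72, 5, n), "sex": rng.choice(["M", "F"], n),
            "stratum": "33", "batch": "b1"}).set_index("sample_id", drop=False)
        x = rng.normal(0, 1, n) + 0.5 * (meta["status"] == "AD").to_numpy()
        values = pd.Series(x, index=meta.index, name="APT1")
        res = st.fit_association(values, meta)
        y = (meta["status"] == "AD").to_numpy(float)
        X = np.column_stack([np.ones(n), meta["age"],
                             (meta["sex"] == "M").astype(float), x])
        opt = optimize.minimize(logit_nll, np.zeros(4), args=(y, X),
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        assert res.converged
        assert res.beta == pytest.approx(opt.x[-1], abs=1e-4)

    def test_perfect_separation_unconverged(self):
        n = 40
        meta = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": ["AD"] * 20 + ["CO"] * 20,
            "age": np.random.default_rng(1).normal(70, 5, n),
            "sex": ["M", "F"] * 20, "stratum": "33",
            "batch": "b1"}).set_index("sample_id", drop=False)
        values = pd.Series((meta["status"] == "AD").astype(float),
                           index=meta.index, name="APT1")
        res = st.fit_association(values, meta)
        assert not res.converged
        assert np.isnan(res.p)

    def test_zero_variance_unconverged(self, toy_metadata):
        values = pd.Series(1.0, index=toy_metadata.index, name="APT1")
        res = st.fit_association(values, toy_metadata)
        assert not res.converged and "zero-variance" in res.reason

    def test_one_class_error(self, toy_metadata):
        meta = toy_metadata[toy_metadata["status"] == "AD"]
        values = pd.Series(np.random.default_rng(2).normal(size=len(meta)),
                           index=meta.index, name="APT1")
        with pytest.raises(st.DegenerateInputError, match="one outcome class"):
            st.fit_association(values, meta)

    def test_casewise_deletion_recorded(self, toy_metadata):
        rng = np.random.default_rng(3)
        values = pd.Series(rng.normal(size=len(toy_metadata)),
                           index=toy_metadata.index, name="APT1")
        values.iloc[:5] = np.nan
        res = st.fit_association(values, toy_metadata)
        assert res.n_used == len(toy_metadata) - 5

    def test_linear_model_is_mean_difference(self, toy_metadata):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, len(toy_metadata))
        values = pd.Series(x, index=toy_metadata.index, name="APT1")
        res = st.fit_association(values, toy_metadata, model="linear")
        y = (toy_metadata["status"] == "AD").astype(float)
        X = sm.add_constant(pd.DataFrame({
            "status": y, "age": toy_metadata["age"],
            "sex": (toy_metadata["sex"] == "M").astype(float)}))
        ref = sm.OLS(x, X).fit()
        assert res.beta == pytest.approx(ref.params["status"], abs=1e-12)
        assert res.p == pytest.approx(ref.pvalues["status"], abs=1e-12)


# ----------------------------------------------------------------------
# IVW meta-analysis
# ----------------------------------------------------------------------

def make_result(beta, se, p=0.5, analyte="A1", stage="discovery",
                converged=True):
    return AssociationResult(analyte, "33", stage, "logistic", beta, se, p,
                             100, converged)


class TestIVW:
    def test_symmetric_pair(self):
        res = st.ivw_meta(make_result(0.4, 0.1),
                          make_result(0.4, 0.1, stage="replication"))
        assert res.beta_pooled == pytest.approx(0.4)
        assert res.se_pooled == pytest.approx(0.1 / np.sqrt(2))

    def test_worked_example(self):
        # beta=(0.5,0.3), se=(0.2,0.1): w=(25,100), pooled=0.34,
        # se=1/sqrt(125), chi2=14.45, p=chi2_1 upper tail
        res = st.ivw_meta(make_result(0.5, 0.2),
                          make_result(0.3, 0.1, stage="replication"))
        assert res.beta_pooled == pytest.approx(0.34, abs=1e-12)
        assert res.se_pooled == pytest.approx(0.0894427, abs=1e-6)
        assert res.chi2 == pytest.approx(14.45, abs=1e-10)
        assert res.p_meta == pytest.approx(stats.chi2.sf(14.45, 1), rel=1e-12)
        assert res.p_meta == pytest.approx(1.4e-4, abs=2e-5)

    def test_null_point(self):
        res = st.ivw_meta(make_result(0.0, 0.1),
                          make_result(0.0, 0.2, stage="replication"))
        assert res.chi2 == 0.0 and res.p_meta == 1.0

    def test_unconverged_stage_missing_meta(self):
        res = st.ivw_meta(make_result(0.5, 0.2),
                          make_result(np.nan, np.nan, converged=False,
                                      stage="replication"))
        assert np.isnan(res.beta_pooled) and np.isnan(res.p_meta)

    def test_chi2_identity(self):
        rng = np.random.default_rng(5)
        b, s, chi2, p = st.ivw_pool(rng.normal(size=(50, 2)),
                                    rng.uniform(0.05, 0.5, (50, 2)))
        np.testing.assert_allclose(chi2, (b / s) ** 2, rtol=1e-12)

    def test_matches_wls_pooling_oracle(self):
        """IVW equals intercept-only weighted-least-squares pooling."""
        rng = np.random.default_rng(6)
        for _ in range(200):
            betas = rng.normal(size=2)
            ses = rng.uniform(0.01, 1.0, 2)
            b, s, _, _ = st.ivw_pool(betas, ses)
            fit = sm.WLS(betas, np.ones((2, 1)), weights=1 / ses ** 2).fit()
            assert b == pytest.approx(fit.params[0], abs=1e-12)
            se_wls = np.sqrt(fit.normalized_cov_params[0, 0])
            assert s == pytest.approx(se_wls, abs=1e-12)

    @given(hs.floats(0.01, 1.0), hs.floats(0.01, 1.0),
           hs.floats(-2, 2), hs.floats(-2, 2))
    @settings(max_examples=50, deadline=None)
    def test_shrinking_se_pulls_pooled_toward_that_beta(self, s1, s2, b1, b2):
        pooled, *_ = st.ivw_pool(np.array([b1, b2]), np.array([s1, s2]))
        tighter, *_ = st.ivw_pool(np.array([b1, b2]), np.array([s1 / 2, s2]))
        assert abs(tighter - b1) <= abs(pooled - b1) + 1e-12


# ----------------------------------------------------------------------
# BH FDR
# ----------------------------------------------------------------------

def bh_bruteforce(p):
    """Literal step-up: q_(i) = min over j>=i of p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(st.bh_fdr([0.01, 0.02, 0.03, 0.5]),
                                   [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_single_and_tied(self):
        assert st.bh_fdr([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(st.bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_missing_passthrough(self):
        out = st.bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_bruteforce([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(st.StratomicsError):
            st.bh_fdr([0.0, 0.5])
        with pytest.raises(st.StratomicsError):
            st.bh_fdr([1.5])

    def test_all_orderings_of_six_match_bruteforce(self):
        base = np.array([0.001, 0.008, 0.039, 0.041, 0.2, 0.9])
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            np.testing.assert_allclose(st.bh_fdr(p), bh_bruteforce(p),
                                       atol=1e-12)

    @given(hs.lists(hs.floats(1e-12, 1.0, exclude_min=False), min_size=1,
                    max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests
        ours = st.bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


# ----------------------------------------------------------------------
# calling, joint and sensitivity
# ----------------------------------------------------------------------

class TestCalling:
    def frame(self, **overrides):
        base = dict(analyte_id=["A1"], stratum=["33"], model=["logistic"],
                    beta_disc=[0.5], se_disc=[0.1], p_disc=[0.04],
                    beta_rep=[0.4], se_rep=[0.1], p_rep=[0.03],
                    beta=[0.45], se=[0.07], chi2=[40.0], p=[1e-9],
                    fdr=[0.04])
        base.update(overrides)
        return pd.DataFrame(base)

    def test_rule_applies(self):
        out = st.call_analytes(self.frame())
        assert out["called"].iloc[0] and out["direction"].iloc[0] == "up"

    def test_opposite_stage_signs_block_call(self):
        out = st.call_analytes(self.frame(beta_rep=[-0.4]))
        assert not out["called"].iloc[0]

    @pytest.mark.parametrize("field,value", [
        ("fdr", 0.051), ("p_disc", 0.06), ("p_rep", 0.0501)])
    def test_boundaries(self, field, value):
        out = st.call_analytes(self.frame(**{field: [value]}))
        assert not out["called"].iloc[0]

    def test_fdr_never_below_p(self, small_cohort):
        _, meta, _, norm, split = small_cohort
        disc = st.fit_stage(norm.data[meta.index[split == "discovery"]],
                            meta[split == "discovery"], stratum="33")
        rep = st.fit_stage(norm.data[meta.index[split == "replication"]],
                           meta[split == "replication"], stratum="33")
        pooled = st.meta_analyze(disc, rep)
        ok = pooled["p"].notna()
        assert (pooled.loc[ok, "fdr"] >= pooled.loc[ok, "p"] - 1e-15).all()


class TestJointAndSensitivity:
    def test_duplicated_halves_joint_equals_half(self, toy_metadata):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, len(toy_metadata)) \
            + 0.8 * (toy_metadata["status"] == "AD").to_numpy()
        values = pd.Series(x, index=toy_metadata.index, name="APT1")
        half = st.fit_association(values, toy_metadata)
        doubled_meta = pd.concat([toy_metadata, toy_metadata.set_index(
            toy_metadata.index + "_dup")])
        doubled_values = pd.concat([values, values.set_axis(
            values.index + "_dup")])
        joint = st.joint_analysis(doubled_values, doubled_meta)
        assert joint.beta == pytest.approx(half.beta, abs=1e-6)

    def test_identity_concordance(self, small_cohort):
        _, meta, _, norm, split = small_cohort
        disc = st.fit_stage(norm.data[meta.index[split == "discovery"]],
                            meta[split == "discovery"], stratum="33")
        rep = st.fit_stage(norm.data[meta.index[split == "replication"]],
                           meta[split == "replication"], stratum="33")
        pooled = st.meta_analyze(disc, rep)
        summary = st.sensitivity_concordance(pooled, pooled)
        assert summary.direction_agreement == 1.0
        assert summary.pearson_r_beta == pytest.approx(1.0)
        assert summary.r2_neglog10_p == pytest.approx(1.0)

    def test_sign_flip_gives_zero_agreement(self, small_cohort):
        _, meta, _, norm, split = small_cohort
        disc = st.fit_stage(norm.data[meta.index[split == "discovery"]],
                            meta[split == "discovery"], stratum="33")
        rep = st.fit_stage(norm.data[meta.index[split == "replication"]],
                           meta[split == "replication"], stratum="33")
        pooled = st.meta_analyze(disc, rep)
        flipped = pooled.copy()
        flipped["beta"] = -flipped["beta"]
        summary = st.sensitivity_concordance(pooled, flipped)
        assert summary.direction_agreement == 0.0
        assert summary.pearson_r_beta == pytest.approx(-1.0)

    def test_too_few_common_analytes_error(self):
        a = pd.DataFrame({"analyte_id": ["A1", "A2"], "beta": [1.0, 2.0],
                          "p": [0.1, 0.2]})
        with pytest.raises(st.DegenerateInputError, match="common analytes"):
            st.sensitivity_concordance(a, a)
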