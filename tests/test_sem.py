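"""Stage 2: df accounting, fit statistics, DWLS fitting properties."""

import json

import numpy as np
import pytest

from semdif.sem import (FitResult, MultigroupFactorModel,
                        RestrictedFactorModel, chisq_diff_test, fit_dwls,
                        rmsea_with_ci)
from semdif.stage1 import run_stage1

ITEMS7 = tuple(f"item{i}" for i in range(1, 8))
ITEMS14 = tuple(f"item{i}" for i in range(1, 15))


# ---------------------------------------------------------------------------
# df accounting


def test_df_multigroup_measurement():
    assert MultigroupFactorModel(ITEMS7, constrained=False).count_df() == 28


def test_df_multigroup_no_bias():
    assert MultigroupFactorModel(ITEMS7, constrained=True).count_df() == 40


def test_df_decreases_one_per_freed_parameter():
    m = MultigroupFactorModel(ITEMS7, constrained=True,
                              free_focal_intercepts=("item3",))
    assert m.count_df() == 39
    m2 = MultigroupFactorModel(ITEMS7, constrained=True,
                               free_focal_intercepts=("item3",),
                               free_focal_loadings=("item3",))
    assert m2.count_df() == 38


def test_df_multidim():
    ifac = tuple([0] * 7 + [1] * 7)
    assert RestrictedFactorModel(ITEMS14, ifac, n_factors=2).count_df() == 76
    m = RestrictedFactorModel(ITEMS14, ifac, n_factors=2,
                              violators=("gender", "age"))
    assert m.count_df() == 100
    free = tuple((f"item{i}", v) for i, v in
                 [(1, "gender"), (5, "gender"), (6, "gender"), (7, "gender"),
                  (13, "gender"), (14, "gender"), (1, "age"), (5, "age"),
                  (6, "age"), (8, "age"), (11, "age"), (12, "age")])
    m12 = RestrictedFactorModel(ITEMS14, ifac, n_factors=2,
                                violators=("gender", "age"), free_direct=free)
    assert m12.count_df() == 88


# ---------------------------------------------------------------------------
# RMSEA arithmetic


@pytest.mark.parametrize("chisq,df,groups,want", [
    (50.64, 28, 2, 0.039),
    (126.4, 40, 2, 0.064),
    (485.05, 76, 1, 0.071),
    (1029.8, 100, 1, 0.093),
])
def test_rmsea_published_values(chisq, df, groups, want):
    rmsea, lo, hi = rmsea_with_ci(chisq, df, 1068, n_groups=groups)
    assert round(rmsea, 3) == want
    assert lo < rmsea < hi


def test_rmsea_truncates_at_zero():
    rmsea, lo, _ = rmsea_with_ci(20.0, 28, 1000, n_groups=2)
    assert rmsea == 0.0
    assert lo == 0.0


def test_rmsea_ci_published_example():
    _, lo, hi = rmsea_with_ci(50.64, 28, 1068, n_groups=2)
    assert round(lo, 3) == pytest.approx(0.021, abs=0.001)
    assert round(hi, 3) == pytest.approx(0.056, abs=0.001)


# ---------------------------------------------------------------------------
# chi-square difference bookkeeping


def _fit_like(chisq, df):
    return FitResult(model=None, estimates={}, robust_ses={},
                     chisq_wls=chisq, df=df, p_value=np.nan, rmsea=np.nan,
                     rmsea_ci=(np.nan, np.nan), converged=True, n_total=1068,
                     n_groups=2, discrepancy=0.0, theta=np.zeros(1))


def test_diff_bookkeeping_published():
    diff, dd, p, warn = chisq_diff_test(_fit_like(126.4, 40), _fit_like(50.64, 28))
    assert diff == pytest.approx(75.76)
    assert dd == 12
    assert p < 0.001
    assert not warn


def test_diff_identical_models():
    diff, dd, p, warn = chisq_diff_test(_fit_like(30.0, 28), _fit_like(30.0, 28))
    assert diff == 0.0 and dd == 0 and p == 1.0


def test_diff_negative_warns():
    diff, dd, p, warn = chisq_diff_test(_fit_like(25.0, 40), _fit_like(30.0, 28))
    assert warn and p == 1.0


# ---------------------------------------------------------------------------
# DWLS fitting properties


def test_fit_converges_and_reports(mg_clean_stage1):
    fit = fit_dwls(MultigroupFactorModel(ITEMS7, constrained=True),
                   mg_clean_stage1)
    assert fit.converged
    assert fit.df == 40
    assert fit.chisq_wls >= 0.0
    assert 0 <= fit.p_value <= 1
    lam = [fit.estimates[f"lambda[{it}]"] for it in ITEMS7]
    assert np.all(np.array(lam) > 0.3)
    assert set(fit.robust_ses) == set(fit.estimates)
    assert all(v > 0 for v in fit.robust_ses.values())


def test_monotonicity_of_discrepancy(mg_dif_stage1):
    base = fit_dwls(MultigroupFactorModel(ITEMS7, constrained=True),
                    mg_dif_stage1, compute_se=False)
    freed = fit_dwls(MultigroupFactorModel(ITEMS7, constrained=True,
                                           free_focal_intercepts=("item3",)),
                     mg_dif_stage1, compute_se=False)
    assert freed.discrepancy <= base.discrepancy + 1e-10


def test_fit_invariant_to_item_reordering(mg_dif_data):
    s1a = run_stage1(mg_dif_data, design="multigroup")
    perm = ["item4", "item1", "item7", "item3", "item2", "item6", "item5"]
    shuffled = type(mg_dif_data)(
        responses=mg_dif_data.responses[perm], group=mg_dif_data.group,
        covariates=None)
    s1b = run_stage1(shuffled, design="multigroup")
    fa = fit_dwls(MultigroupFactorModel(tuple(s1a.item_names), True), s1a,
                  compute_se=False)
    fb = fit_dwls(MultigroupFactorModel(tuple(perm), True), s1b,
                  compute_se=False)
    assert fa.chisq_wls == pytest.approx(fb.chisq_wls, rel=1e-4, abs=1e-3)
    for it in perm:
        assert fa.estimates[f"lambda[{it}]"] == pytest.approx(
            fb.estimates[f"lambda[{it}]"], abs=1e-4)


def test_exact_moments_recover_parameters(mg_clean_stage1):
    """Moments generated from the model itself are fitted exactly."""
    model = MultigroupFactorModel(ITEMS7, constrained=True)
    fit0 = fit_dwls(model, mg_clean_stage1, compute_se=False)
    s1 = mg_clean_stage1
    synth = type(s1)(
        design=s1.design, item_names=s1.item_names,
        covariate_names=s1.covariate_names, thresholds=s1.thresholds,
        n_categories=s1.n_categories, corr=s1.corr, foc_means=s1.foc_means,
        foc_sds=s1.foc_sds, pair_rmsea=s1.pair_rmsea,
        flagged_pairs=s1.flagged_pairs,
        moments=s1.moments.copy(), moment_labels=s1.moment_labels,
        acov=s1.acov, n_total=s1.n_total, n_per_group=s1.n_per_group)
    idx = synth.index_of(model.moment_labels())
    synth.moments[idx] = model.implied(fit0.theta)
    refit = fit_dwls(model, synth, compute_se=False)
    assert refit.discrepancy == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(refit.theta, fit0.theta, atol=1e-4)
    assert refit.chisq_wls == pytest.approx(0.0, abs=1e-6)


def test_fit_result_json_round_trip(mg_clean_stage1):
    fit = fit_dwls(MultigroupFactorModel(ITEMS7, constrained=True),
                   mg_clean_stage1)
    d = fit.to_json_dict()
    text = json.dumps(d)
    back = json.loads(text)
    assert back["df"] == 40
    assert back["converged"] is True
    names = {row["name"] for row in back["parameters"]}
    assert "kappa_foc" in names and "phi_foc" in names
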