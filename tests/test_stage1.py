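"""Stage 1 estimators: closed-form oracles, grid-search oracles, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from semdif._bvn import cell_probabilities
from semdif.generate import make_hads_like_spec, simulate
from semdif.stage1 import (bivariate_normality_rmsea, bootstrap_acov,
                           estimate_polychoric, estimate_thresholds,
                           joint_margin_ml, polyserial_correlation,
                           run_stage1)

# ---------------------------------------------------------------------------
# thresholds


def test_thresholds_closed_form():
    tau = estimate_thresholds(np.array([100, 200, 300, 400]))
    assert np.allclose(tau, norm.ppf([0.1, 0.3, 0.6]), atol=1e-12)


def test_thresholds_collapse_empty_extremes():
    tau = estimate_thresholds(np.array([0, 500, 500, 0]))
    assert tau.shape == (1,)
    assert tau[0] == pytest.approx(0.0, abs=1e-12)


def test_thresholds_interior_pseudocount():
    tau = estimate_thresholds(np.array([500, 0, 500]))
    assert tau.shape == (2,)
    assert np.all(np.diff(tau) > 0)
    assert tau[0] == pytest.approx(-tau[1])


def test_thresholds_too_few_categories():
    with pytest.raises(ValueError, match="2 observed categories"):
        estimate_thresholds(np.array([0, 700, 0]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=500),
                min_size=2, max_size=6))
def test_thresholds_increasing_property(counts):
    tau = estimate_thresholds(np.array(counts))
    assert len(tau) == len(counts) - 1
    assert np.all(np.diff(tau) > 0)
    assert np.all(np.isfinite(tau))


# ---------------------------------------------------------------------------
# polychoric correlation


def _random_table(rng, rho, n=600, K=4):
    cuts = norm.ppf(np.cumsum(rng.dirichlet(np.ones(K)))[:-1])
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.searchsorted(cuts, z[:, 0])
    y = np.searchsorted(cuts, z[:, 1])
    tab = np.zeros((K, K))
    np.add.at(tab, (x, y), 1.0)
    return tab


def _grid_argmax(tab, za, zb, lo=-0.995, hi=0.995, n=500):
    grid = np.linspace(lo, hi, n)
    ll = [np.sum(tab * np.log(cell_probabilities(za, zb, r))) for r in grid]
    k = int(np.argmax(ll))
    # refine once around the best grid point
    fine = np.linspace(grid[max(k - 1, 0)], grid[min(k + 1, n - 1)], 400)
    llf = [np.sum(tab * np.log(cell_probabilities(za, zb, r))) for r in fine]
    return float(fine[int(np.argmax(llf))])


def test_polychoric_matches_grid_oracle():
    rng = np.random.default_rng(7)
    for _ in range(8):
        rho_true = rng.uniform(-0.85, 0.85)
        tab = _random_table(rng, rho_true)
        za = estimate_thresholds(tab.sum(axis=1))
        zb = estimate_thresholds(tab.sum(axis=0))
        rho, se, boundary = estimate_polychoric(tab, za, zb)
        assert not boundary
        assert rho == pytest.approx(_grid_argmax(tab, za, zb), abs=1e-3)
        assert 0 < se < 0.2


def test_polychoric_transposition_symmetry():
    rng = np.random.default_rng(11)
    tab = _random_table(rng, 0.5)
    za = estimate_thresholds(tab.sum(axis=1))
    zb = estimate_thresholds(tab.sum(axis=0))
    r1, _, _ = estimate_polychoric(tab, za, zb)
    r2, _, _ = estimate_polychoric(tab.T, zb, za)
    assert r1 == pytest.approx(r2, abs=1e-6)


def test_polychoric_sign_flip():
    rng = np.random.default_rng(13)
    tab = _random_table(rng, 0.6)
    za = estimate_thresholds(tab.sum(axis=1))
    zb = estimate_thresholds(tab.sum(axis=0))
    r1, _, _ = estimate_polychoric(tab, za, zb)
    r2, _, _ = estimate_polychoric(tab[:, ::-1], za, -zb[::-1])
    assert r2 == pytest.approx(-r1, abs=1e-5)


def test_polychoric_boundary_flag():
    # perfectly concordant table drives rho to the boundary
    tab = np.diag([50.0, 50, 50, 50])
    cuts = norm.ppf([0.25, 0.5, 0.75])
    rho, se, boundary = estimate_polychoric(tab, cuts, cuts)
    assert boundary
    assert rho > 0.99


def test_bivariate_normality_rmsea_small_for_normal_data():
    rng = np.random.default_rng(17)
    tab = _random_table(rng, 0.4, n=2000)
    za = estimate_thresholds(tab.sum(axis=1))
    zb = estimate_thresholds(tab.sum(axis=0))
    rho, _, _ = estimate_polychoric(tab, za, zb)
    assert bivariate_normality_rmsea(tab, rho, za, zb) < 0.1


# ---------------------------------------------------------------------------
# polyserial correlation


def test_polyserial_recovers_known_rho():
    rng = np.random.default_rng(23)
    rho_true = 0.45
    n = 4000
    z = rng.multivariate_normal([0, 0], [[1, rho_true], [rho_true, 1]], size=n)
    cuts = norm.ppf([0.35, 0.65, 0.85])
    x = np.searchsorted(cuts, z[:, 0])
    w = 10.0 + 3.0 * z[:, 1]  # location/scale must not matter
    tau = estimate_thresholds(np.bincount(x, minlength=4))
    r = polyserial_correlation(x, w, tau)
    assert r == pytest.approx(rho_true, abs=0.04)
    assert polyserial_correlation(x, -w, tau) == pytest.approx(-r, abs=1e-5)


def test_polyserial_constant_covariate_errors():
    with pytest.raises(ValueError, match="zero variance"):
        polyserial_correlation(np.array([0, 1, 2]), np.ones(3), np.array([-0.5, 0.5]))


# ---------------------------------------------------------------------------
# joint margin ML (multigroup scale fixing)


def test_joint_margin_ml_equal_groups():
    cnt = np.array([300.0, 300, 250, 150])
    tau, mu, sig, psi = joint_margin_ml(cnt, cnt)
    assert mu == pytest.approx(0.0, abs=1e-6)
    assert sig == pytest.approx(1.0, abs=1e-6)
    assert np.allclose(tau, norm.ppf(np.cumsum(cnt)[:-1] / cnt.sum()), atol=1e-6)
    assert psi.shape == (2, 4, 5)


def test_joint_margin_ml_recovers_shift_and_scale():
    mu_t, sig_t = 0.4, 1.3
    cuts = norm.ppf([0.3, 0.6, 0.85])
    n = 200000
    rng = np.random.default_rng(3)
    xr = np.searchsorted(cuts, rng.standard_normal(n))
    xf = np.searchsorted(cuts, mu_t + sig_t * rng.standard_normal(n))
    tau, mu, sig, _ = joint_margin_ml(np.bincount(xr, minlength=4),
                                      np.bincount(xf, minlength=4))
    assert np.allclose(tau, cuts, atol=0.02)
    assert mu == pytest.approx(mu_t, abs=0.02)
    assert sig == pytest.approx(sig_t, abs=0.03)


def test_joint_margin_ml_binary_fixes_sigma():
    tau, mu, sig, psi = joint_margin_ml(np.array([600.0, 400]),
                                        np.array([450.0, 550]))
    assert sig == 1.0
    assert tau[0] == pytest.approx(norm.ppf(0.6), abs=1e-6)
    assert mu == pytest.approx(tau[0] - norm.ppf(0.45), abs=1e-6)
    assert np.allclose(psi[:, :, 2], 0.0)  # sigma column inert


# ---------------------------------------------------------------------------
# full Stage 1 runs


def test_stage1_multigroup_layout(mg_clean_stage1):
    s1 = mg_clean_stage1
    p = 7
    n_pair = p * (p - 1) // 2
    assert len(s1.moments) == 2 * n_pair + 2 * p == 56
    kinds = [lab[0] for lab in s1.moment_labels]
    assert kinds[:n_pair] == ["corr_ref"] * n_pair
    assert kinds[n_pair:n_pair + p] == ["mean_foc"] * p
    assert kinds[n_pair + p:n_pair + 2 * p] == ["sd_foc"] * p
    assert kinds[n_pair + 2 * p:] == ["corr_foc"] * n_pair
    assert s1.acov.shape == (56, 56)
    assert np.allclose(s1.acov, s1.acov.T)
    assert np.all(np.linalg.eigvalsh(s1.acov) > -1e-8)


def test_stage1_clean_groups_have_similar_moments(mg_clean_stage1):
    s1 = mg_clean_stage1
    # no DIF and equal latent distributions: focal means ~0, sds ~1
    assert np.all(np.abs(s1.foc_means) < 0.15)
    assert np.all(np.abs(s1.foc_sds - 1.0) < 0.2)
    r_ref = s1.corr["ref"].to_numpy()
    r_foc = s1.corr["foc"].to_numpy()
    assert np.max(np.abs(r_ref - r_foc)) < 0.2


def test_stage1_single_design_layout(md_stage1):
    s1 = md_stage1
    p, nv = 14, 2
    want = p * (p - 1) // 2 + p * nv + nv * (nv - 1) // 2
    assert len(s1.moments) == want == 120
    assert s1.corr["all"].shape == (16, 16)
    # violator-violator correlation equals product-moment of standardized
    wz = (md_stage1.corr["all"].loc["gender", "age"])
    assert -1 < wz < 1


def test_stage1_acov_matches_bootstrap(mg_dif_data, mg_dif_stage1):
    G_if = mg_dif_stage1.acov
    G_b = bootstrap_acov(mg_dif_data, design="multigroup", n_boot=60, seed=1)
    ratio = np.sqrt(np.diag(G_if)) / np.sqrt(np.diag(G_b))
    # bootstrap with B=60 is noisy; check agreement in aggregate
    assert abs(np.mean(ratio) - 1.0) < 0.1
    assert np.all(ratio > 0.6) and np.all(ratio < 1.6)


def test_stage1_requires_group_for_multigroup():
    spec = make_hads_like_spec("two_factor_14")
    d = simulate(spec, n_per_group=200, seed=0)
    with pytest.raises(ValueError, match="group"):
        run_stage1(d, design="multigroup")


def test_stage1_rejects_unknown_design(mg_clean_data):
    with pytest.raises(ValueError, match="design"):
        run_stage1(mg_clean_data, design="bogus")


def test_stage1_covariates_only_in_single_design(mg_clean_data):
    with pytest.raises(ValueError, match="single"):
        run_stage1(mg_clean_data, design="multigroup", covariate_names=["x"])
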