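"""Stage 1: moments of the continuous variables underlying ordinal items.

Observed ordinal responses are modeled as discretizations of latent normal
variables.  This module estimates, per design:

* item thresholds from pooled cumulative proportions (equal across groups
  in the multigroup design);
* polychoric correlations between item pairs (two-step maximum likelihood
  with thresholds fixed), polyserial correlations between items and
  continuous covariates, and product-moment correlations among covariates;
* in the multigroup design, the focal group's underlying means and SDs
  relative to the shared thresholds (the reference group is standardized);
* a per-pair bivariate-normality diagnostic (RMSEA of the fitted table);
* the asymptotic covariance matrix of the whole stacked moment vector,
  assembled from per-observation influence functions (a seeded
  nonparametric bootstrap is available as an independent cross-check).

The moment vector and its asymptotic covariance are the data for Stage 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import chi2, norm

from ._bvn import bvn_pdf, cell_probabilities
from .generate import OrdinalDataset

RHO_BOUND = 0.999
RMSEA_PAIR_CUTOFF = 0.1


# ---------------------------------------------------------------------------
# thresholds


def estimate_thresholds(category_counts: np.ndarray) -> np.ndarray:
    """Thresholds as normal quantiles of cumulative category proportions.

    Empty extreme categories are collapsed into their neighbors; interior
    empty categories receive a 0.5 pseudo-count so all thresholds stay
    finite and strictly increasing.
    """
    counts = np.asarray(category_counts, dtype=float)
    nz = np.nonzero(counts)[0]
    if nz.size < 2:
        raise ValueError("item needs at least 2 observed categories")
    counts = counts[nz[0]: nz[-1] + 1].copy()
    counts[counts == 0] = 0.5
    cum = np.cumsum(counts)[:-1] / counts.sum()
    tau = norm.ppf(cum)
    if np.any(np.diff(tau) <= 0):  # cannot happen with positive counts
        raise ValueError("thresholds not strictly increasing")
    return tau


def _recode_map(category_counts: np.ndarray) -> np.ndarray:
    """Map original categories onto the collapsed coding used for thresholds."""
    counts = np.asarray(category_counts)
    nz = np.nonzero(counts)[0]
    return np.clip(np.arange(len(counts)), nz[0], nz[-1]) - nz[0]


# ---------------------------------------------------------------------------
# polychoric likelihood machinery


def _poly_loglik(rho: float, table: np.ndarray, za: np.ndarray, zb: np.ndarray) -> float:
    p = cell_probabilities(za, zb, rho)
    return float(np.sum(table * np.log(p)))


def _dpi_drho(za: np.ndarray, zb: np.ndarray, rho: float) -> np.ndarray:
    """d(cell probability)/d(rho): differences of the bivariate density."""
    a = np.concatenate([[-np.inf], za, [np.inf]])
    b = np.concatenate([[-np.inf], zb, [np.inf]])
    F = bvn_pdf(a[:, None], b[None, :], rho)
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


def _poly_score(rho: float, phat: np.ndarray, za: np.ndarray, zb: np.ndarray):
    """Mean score for rho and the per-cell score values u."""
    p = cell_probabilities(za, zb, rho)
    u = _dpi_drho(za, zb, rho) / p
    return float(np.sum(phat * u)), u


def estimate_polychoric(table: np.ndarray, thresholds_row: np.ndarray,
                        thresholds_col: np.ndarray) -> tuple[float, float, bool]:
    """Two-step ML polychoric correlation with thresholds held fixed.

    Returns ``(rho, se, boundary_flag)``; the estimate is clipped to
    ``[-0.999, 0.999]`` and the flag marks degenerate/boundary solutions.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("contingency table must have positive total")
    za = np.asarray(thresholds_row, float)
    zb = np.asarray(thresholds_col, float)
    res = minimize_scalar(lambda r: -_poly_loglik(r, table, za, zb),
                          bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-7})
    rho = float(res.x)
    boundary = abs(rho) >= RHO_BOUND - 1e-4 or np.count_nonzero(table) == 1
    # SE from numeric observed information of the mean log-likelihood
    h = 1e-4
    ll = lambda r: _poly_loglik(r, table / n, za, zb)
    d2 = (ll(rho + h) - 2.0 * ll(rho) + ll(rho - h)) / h**2
    se = float(np.sqrt(1.0 / (n * max(-d2, 1e-12)))) if not boundary else np.nan
    return rho, se, boundary


def bivariate_normality_rmsea(table: np.ndarray, rho: float,
                              tau_row: np.ndarray, tau_col: np.ndarray) -> float:
    """RMSEA of the bivariate-normal model for one contingency table.

    Pearson chi-square of observed vs model-implied counts with
    df = (R*C - 1) - 1 (thresholds fixed from the univariate margins, one
    correlation fitted).
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    pi = cell_probabilities(np.asarray(tau_row, float), np.asarray(tau_col, float), rho)
    chisq = float(np.sum((table - n * pi) ** 2 / (n * pi)))
    df = table.size - 2
    return float(np.sqrt(max(0.0, (chisq - df) / (df * n))))


# ---------------------------------------------------------------------------
# polyserial likelihood machinery


def _polyserial_loglik_terms(rho: float, tau: np.ndarray, w: np.ndarray,
                             cat: np.ndarray):
    s = np.sqrt(1.0 - rho * rho)
    cuts = np.concatenate([[-np.inf], tau, [np.inf]])
    vu = (cuts[cat + 1] - rho * w) / s
    vl = (cuts[cat] - rho * w) / s
    pu, pl = norm.cdf(vu), norm.cdf(vl)
    pr = np.clip(pu - pl, 1e-300, None)
    return vu, vl, pr, s


def _polyserial_loglik(rho, tau, w, cat) -> float:
    _, _, pr, _ = _polyserial_loglik_terms(rho, tau, w, cat)
    return float(np.sum(np.log(pr)))


def _polyserial_scores(rho, tau, w, cat) -> np.ndarray:
    """Per-observation d(loglik)/d(rho)."""
    vu, vl, pr, s = _polyserial_loglik_terms(rho, tau, w, cat)
    # dv/drho = -w/s + rho*v/s^2
    dvu = np.where(np.isfinite(vu), -w / s + rho * vu / s**2, 0.0)
    dvl = np.where(np.isfinite(vl), -w / s + rho * vl / s**2, 0.0)
    return (norm.pdf(np.where(np.isfinite(vu), vu, 0.0)) * np.isfinite(vu) * dvu
            - norm.pdf(np.where(np.isfinite(vl), vl, 0.0)) * np.isfinite(vl) * dvl) / pr


def polyserial_correlation(x_ord: np.ndarray, w: np.ndarray,
                           thresholds: np.ndarray) -> float:
    """Two-step ML polyserial correlation; item thresholds fixed, covariate
    standardized internally."""
    w = np.asarray(w, dtype=float)
    if np.std(w) == 0:
        raise ValueError("covariate has zero variance")
    wz = (w - w.mean()) / w.std()
    cat = np.asarray(x_ord, dtype=int)
    res = minimize_scalar(lambda r: -_polyserial_loglik(r, thresholds, wz, cat),
                          bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x)


# ---------------------------------------------------------------------------
# focal-group underlying means / SDs


def _fit_focal_moments(tau: np.ndarray, cum_foc: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of Phi((tau - mu)/sigma) to focal cumulative props
    (used as starting values for the joint margin ML)."""

    def resid(b):
        mu, sig = b
        return norm.cdf((tau - mu) / sig) - cum_foc

    sol = least_squares(resid, x0=np.array([0.0, 1.0]),
                        bounds=([-5.0, 0.05], [5.0, 20.0]), xtol=1e-12, ftol=1e-12)
    return float(sol.x[0]), float(sol.x[1])


def _margin_probs(tau, mu, sig):
    z = np.concatenate([[-np.inf], (tau - mu) / sig, [np.inf]])
    P = norm.cdf(z)
    return np.clip(np.diff(P), 1e-12, None), z


def joint_margin_ml(cnt_ref: np.ndarray, cnt_foc: np.ndarray):
    """Shared thresholds with the reference group standardized.

    Maximizes the two groups' marginal multinomial likelihood over
    (tau, mu_foc, sigma_foc) with the reference underlying variable fixed
    to N(0, 1) and the focal one N(mu, sigma^2) -- the equal-thresholds
    identification of the multigroup design.  Returns the estimates plus a
    per-(group, category) influence-function table for
    [tau_1..tau_{K-1}, mu, sigma].
    """
    cnt_ref = np.asarray(cnt_ref, float)
    cnt_foc = np.asarray(cnt_foc, float)
    K = len(cnt_ref)
    N = cnt_ref.sum() + cnt_foc.sum()
    est_sig = K > 2  # with 2 categories sigma_foc is not identified; fix at 1
    tau0 = norm.ppf(np.clip(np.cumsum(cnt_ref)[:-1] / cnt_ref.sum(), 1e-4, 1 - 1e-4))
    tau0 = np.maximum.accumulate(tau0 + 1e-6 * np.arange(K - 1))
    cum_f = np.cumsum(cnt_foc)[:-1] / cnt_foc.sum()
    mu0, sig0 = _fit_focal_moments(tau0, np.clip(cum_f, 1e-4, 1 - 1e-4))
    if not est_sig:
        sig0 = 1.0

    def grad_nat(theta):
        """Gradient of the negative mean log-likelihood, natural params
        [tau_1..tau_{K-1}, mu, sigma] (sigma dropped when fixed)."""
        tau, mu = theta[:K - 1], theta[K - 1]
        sig = theta[K] if est_sig else 1.0
        pr, zr = _margin_probs(tau, 0.0, 1.0)
        pf, zf = _margin_probs(tau, mu, sig)
        wr, wf = cnt_ref / N, cnt_foc / N
        rr, rf = wr / pr, wf / pf
        g_tau = (norm.pdf(tau) * (rr[:-1] - rr[1:])
                 + norm.pdf(zf[1:-1]) / sig * (rf[:-1] - rf[1:]))
        zsafe = np.where(np.isfinite(zf), zf, 0.0)
        phi_f = norm.pdf(zsafe) * np.isfinite(zf)
        zphi_f = zsafe * phi_f
        g_mu = float(np.sum(rf * -(phi_f[1:] - phi_f[:-1]) / sig))
        g_sig = float(np.sum(rf * -(zphi_f[1:] - zphi_f[:-1]) / sig))
        g = np.concatenate([g_tau, [g_mu, g_sig]] if est_sig else [g_tau, [g_mu]])
        return -g

    npar = K + 1 if est_sig else K

    def to_nat(x):
        tau = np.concatenate([[x[0]], x[0] + np.cumsum(np.exp(x[1:K - 1]))])
        tail = [x[K - 1], np.exp(x[K])] if est_sig else [x[K - 1]]
        return np.concatenate([tau, tail])

    def nll_x(x):
        th = to_nat(x)
        sig = th[K] if est_sig else 1.0
        pr, _ = _margin_probs(th[:K - 1], 0.0, 1.0)
        pf, _ = _margin_probs(th[:K - 1], th[K - 1], sig)
        return -(cnt_ref @ np.log(pr) + cnt_foc @ np.log(pf)) / N

    def grad_x(x):
        th = to_nat(x)
        g = grad_nat(th)
        J = np.zeros((npar, npar))  # d(natural)/d(x)
        J[: K - 1, 0] = 1.0
        for j in range(1, K - 1):
            J[j: K - 1, j] = np.exp(x[j])
        J[K - 1, K - 1] = 1.0
        if est_sig:
            J[K, K] = th[K]
        return J.T @ g

    x0 = np.concatenate([[tau0[0]], np.log(np.maximum(np.diff(tau0), 1e-4)),
                         [mu0, np.log(sig0)] if est_sig else [mu0]])
    from scipy.optimize import minimize as _minimize
    res = _minimize(nll_x, x0, jac=grad_x, method="BFGS",
                    options={"gtol": 1e-10, "maxiter": 300})
    theta = to_nat(res.x)
    tau, mu = theta[:K - 1], float(theta[K - 1])
    sig = float(theta[K]) if est_sig else 1.0

    # influence functions: psi = H^-1 * per-observation score
    from scipy.optimize._numdiff import approx_derivative
    H = approx_derivative(grad_nat, theta, method="2-point",
                          rel_step=1e-6)
    H = (H + H.T) / 2.0
    pr, zr = _margin_probs(tau, 0.0, 1.0)
    pf, zf = _margin_probs(tau, mu, sig)
    score = np.zeros((2, K, npar))
    phi_r = norm.pdf(tau)
    phi_fz = norm.pdf(zf[1:-1])
    for k in range(K):
        if k < K - 1:
            score[0, k, k] += phi_r[k] / pr[k]
            score[1, k, k] += (phi_fz[k] / sig) / pf[k]
        if k > 0:
            score[0, k, k - 1] -= phi_r[k - 1] / pr[k]
            score[1, k, k - 1] -= (phi_fz[k - 1] / sig) / pf[k]
        pu = phi_fz[k] if k < K - 1 else 0.0
        pl = phi_fz[k - 1] if k > 0 else 0.0
        score[1, k, K - 1] += -(pu - pl) / sig / pf[k]
        if est_sig:
            zu = zf[k + 1] * pu if k < K - 1 else 0.0
            zl = zf[k] * pl if k > 0 else 0.0
            score[1, k, K] += -(zu - zl) / sig / pf[k]
    psi_table = np.einsum("ij,gkj->gki", np.linalg.inv(H), score)
    if not est_sig:  # pad a zero sigma column so callers see (2, K, K+1)
        psi_table = np.concatenate(
            [psi_table, np.zeros((2, K, 1))], axis=2)
    return tau, mu, sig, psi_table


# ---------------------------------------------------------------------------
# Stage 1 result container


@dataclass
class Stage1Result:
    design: str  # "multigroup" | "single"
    item_names: list[str]
    covariate_names: list[str]
    thresholds: list[np.ndarray]  # per item, pooled, after collapsing
    n_categories: list[int]
    corr: dict[str, pd.DataFrame]  # "ref"/"foc" or "all"
    foc_means: np.ndarray | None
    foc_sds: np.ndarray | None
    pair_rmsea: pd.DataFrame | None
    flagged_pairs: list[tuple]
    moments: np.ndarray
    moment_labels: list[tuple]
    acov: np.ndarray  # Gamma = asymptotic covariance of sqrt(N) * moments
    n_total: int
    n_per_group: dict[str, int] = field(default_factory=dict)
    boundary_pairs: list[tuple] = field(default_factory=list)

    def index_of(self, labels: list[tuple]) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.moment_labels)}
        return np.array([lut[lab] for lab in labels], dtype=int)

    def to_json_dict(self) -> dict:
        return {
            "design": self.design,
            "item_names": self.item_names,
            "covariate_names": self.covariate_names,
            "thresholds": {nm: t.tolist() for nm, t in zip(self.item_names, self.thresholds)},
            "correlations": {k: v.values.tolist() for k, v in self.corr.items()},
            "focal_means": None if self.foc_means is None else self.foc_means.tolist(),
            "focal_sds": None if self.foc_sds is None else self.foc_sds.tolist(),
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "n_total": self.n_total,
            "n_per_group": self.n_per_group,
        }


# ---------------------------------------------------------------------------
# the full Stage 1 run


def run_stage1(data: OrdinalDataset, design: str = "multigroup",
               covariate_names: list[str] | None = None,
               compute_acov: bool = True) -> Stage1Result:
    """Estimate all Stage 1 moments and their asymptotic covariance."""
    if design not in ("multigroup", "single"):
        raise ValueError("design must be 'multigroup' or 'single'")
    covariate_names = list(covariate_names or [])
    items = data.item_names
    p = len(items)
    X = data.responses.to_numpy(dtype=int)
    if np.any(X < 0):
        raise ValueError("negative response categories not supported")
    N = X.shape[0]

    if design == "multigroup":
        if data.group is None:
            raise ValueError("multigroup design requires a group column")
        g = data.group.to_numpy()
        levels = np.unique(g)
        if len(levels) != 2:
            raise ValueError("group must take exactly two values")
        foc_mask = g == levels[1]
    else:
        foc_mask = np.zeros(N, dtype=bool)
    n_foc = int(foc_mask.sum())
    n_ref = N - n_foc

    # ---- per-item thresholds and category recoding ----------------------
    # multigroup: joint margin ML with shared thresholds, reference
    #   standardized N(0,1), focal N(mu, sigma^2);
    # single: normal quantiles of the cumulative proportions.
    thresholds: list[np.ndarray] = []
    Ks: list[int] = []
    Xr = np.empty_like(X)
    psi_tau: list[np.ndarray] = []     # single design: (K, K-1) lookup
    psi_mg: list[np.ndarray] = []      # multigroup: per-obs (N, K+1) IFs
    foc_means = np.zeros(p) if design == "multigroup" else None
    foc_sds = np.ones(p) if design == "multigroup" else None
    zfoc: list[np.ndarray] = []

    for i in range(p):
        cnt = np.bincount(X[:, i], minlength=int(X[:, i].max()) + 1)
        remap = _recode_map(cnt)
        Xr[:, i] = remap[X[:, i]]

        if design == "multigroup":
            K = int(Xr[:, i].max()) + 1
            if K < 2:
                raise ValueError("item needs at least 2 observed categories")
            cnt_r = np.bincount(Xr[~foc_mask, i], minlength=K).astype(float)
            cnt_f = np.bincount(Xr[foc_mask, i], minlength=K).astype(float)
            # interior categories empty in both groups would make the joint
            # likelihood degenerate; give each group a small pseudo-count
            both_empty = (cnt_r + cnt_f) == 0
            cnt_r[both_empty] = 0.25
            cnt_f[both_empty] = 0.25
            tau, mu, sig, psi_tab = joint_margin_ml(cnt_r, cnt_f)
            thresholds.append(tau)
            Ks.append(K)
            foc_means[i], foc_sds[i] = mu, sig
            zfoc.append((tau - mu) / sig)
            # per-observation IFs for [tau..., mu_foc, sigma_foc]
            psi_mg.append(psi_tab[foc_mask.astype(int), Xr[:, i]])
        else:
            tau = estimate_thresholds(cnt)
            thresholds.append(tau)
            K = len(tau) + 1
            Ks.append(K)
            cum = norm.cdf(tau)  # cumulative proportions actually used
            cats = np.arange(K)
            ind = (cats[:, None] < np.arange(1, K)[None, :]).astype(float)
            psi_tau.append((ind - cum[None, :]) / norm.pdf(tau)[None, :])
            zfoc.append(tau)

    # ---- covariates (single design) -------------------------------------
    W = None
    wz = None
    if covariate_names:
        if design == "multigroup":
            raise ValueError("covariates enter the single-group (RFA) design only")
        W = data.covariates[covariate_names].to_numpy(dtype=float)
        wm, ws = W.mean(axis=0), W.std(axis=0)
        if np.any(ws == 0):
            raise ValueError("constant covariate")
        wz = (W - wm) / ws

    # ---- moment vector + influence functions ----------------------------
    labels: list[tuple] = []
    cols: list[np.ndarray] = []
    w_ref = N / max(n_ref, 1)
    w_foc = N / max(n_foc, 1)

    pair_rmsea = np.zeros((p, p))
    flagged: list[tuple] = []
    boundary: list[tuple] = []
    corr_mats: dict[str, np.ndarray] = {}

    def poly_pair(i, j, mask, za, zb, wg, group_key):
        tab = np.zeros((Ks[i], Ks[j]))
        np.add.at(tab, (Xr[mask, i], Xr[mask, j]), 1.0)
        n = tab.sum()
        res = minimize_scalar(lambda r: -_poly_loglik(r, tab, za, zb),
                              bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                              options={"xatol": 1e-7})
        rho = float(res.x)
        if abs(rho) >= RHO_BOUND - 1e-4:
            boundary.append((group_key, items[i], items[j]))
        phat = tab / n
        _, u = _poly_score(rho, phat, za, zb)
        # numeric partials of the mean score
        h = 1e-5
        S = lambda r, a, b: _poly_score(r, phat, a, b)[0]
        S_rho = (S(rho + h, za, zb) - S(rho - h, za, zb)) / (2 * h)
        dza = np.zeros(len(za))
        for k in range(len(za)):
            e = np.zeros(len(za)); e[k] = h
            dza[k] = (S(rho, za + e, zb) - S(rho, za - e, zb)) / (2 * h)
        dzb = np.zeros(len(zb))
        for k in range(len(zb)):
            e = np.zeros(len(zb)); e[k] = h
            dzb[k] = (S(rho, za, zb + e) - S(rho, za, zb - e)) / (2 * h)
        rm = bivariate_normality_rmsea(tab, rho, za, zb)
        return rho, u, S_rho, dza, dzb, rm, n

    def psi_cut(i, focal: bool) -> np.ndarray:
        """Per-obs influence of each cut point of item i, (N, K-1)."""
        if design == "single":
            return psi_tau[i][Xr[:, i], :]
        arr = psi_mg[i]  # (N, K+1): [tau..., mu, sigma]
        K = Ks[i]
        tau_part = arr[:, : K - 1]
        if not focal:
            return tau_part
        z = zfoc[i]
        return (tau_part - arr[:, [K - 1]] - z[None, :] * arr[:, [K]]) / foc_sds[i]

    cut_cache: dict[tuple, np.ndarray] = {}

    def get_cut(i, focal):
        key = (i, focal)
        if key not in cut_cache:
            cut_cache[key] = psi_cut(i, focal)
        return cut_cache[key]

    if design == "multigroup":
        group_plans = [("ref", ~foc_mask, False, w_ref), ("foc", foc_mask, True, w_foc)]
    else:
        group_plans = [("all", np.ones(N, dtype=bool), False, 1.0)]

    rmsea_frames = {}
    for gkey, mask, focal, wg in group_plans:
        R = np.eye(p)
        rms = np.zeros((p, p))
        psis = {}
        for i in range(p):
            for j in range(i + 1, p):
                za = zfoc[i] if focal else thresholds[i]
                zb = zfoc[j] if focal else thresholds[j]
                rho, u, S_rho, dza, dzb, rm, n = poly_pair(i, j, mask, za, zb, wg, gkey)
                R[i, j] = R[j, i] = rho
                rms[i, j] = rms[j, i] = rm
                if rm > RMSEA_PAIR_CUTOFF:
                    flagged.append((gkey, items[i], items[j], rm))
                col = np.zeros(N)
                col[mask] = wg * u[Xr[mask, i], Xr[mask, j]]
                col += get_cut(i, focal) @ dza + get_cut(j, focal) @ dzb
                psis[(i, j)] = -col / S_rho
        corr_mats[gkey] = R
        rmsea_frames[gkey] = rms
        for i in range(p):
            for j in range(i + 1, p):
                labels.append((f"corr_{gkey}", items[i], items[j]))
                cols.append(psis[(i, j)])

    # multigroup: insert focal means/sds between ref corr and foc corr blocks
    if design == "multigroup":
        mean_cols = [psi_mg[i][:, Ks[i] - 1] for i in range(p)]
        sd_cols = [psi_mg[i][:, Ks[i]] for i in range(p)]
        # reorder: ref corr block is first already; now means, sds, then foc corr
        n_pair = p * (p - 1) // 2
        ref_labels, ref_cols = labels[:n_pair], cols[:n_pair]
        foc_labels, foc_cols = labels[n_pair:], cols[n_pair:]
        labels = (ref_labels
                  + [("mean_foc", items[i]) for i in range(p)]
                  + [("sd_foc", items[i]) for i in range(p)]
                  + foc_labels)
        cols = ref_cols + mean_cols + sd_cols + foc_cols
        moments = np.concatenate([
            corr_mats["ref"][np.triu_indices(p, 1)],
            foc_means, foc_sds,
            corr_mats["foc"][np.triu_indices(p, 1)],
        ])
    else:
        moments = corr_mats["all"][np.triu_indices(p, 1)].copy()

    # ---- single design: item-covariate and covariate-covariate ----------
    if design == "single" and covariate_names:
        nv = len(covariate_names)
        rho_iv = np.zeros((p, nv))
        for d in range(nv):
            for i in range(p):
                tau = thresholds[i]
                cat = Xr[:, i]
                res = minimize_scalar(
                    lambda r: -_polyserial_loglik(r, tau, wz[:, d], cat),
                    bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                    options={"xatol": 1e-7})
                rho = float(res.x)
                rho_iv[i, d] = rho
                # influence function
                h = 1e-5
                sc = _polyserial_scores(rho, tau, wz[:, d], cat)
                Sfun = lambda r, t, m, s: float(np.mean(_polyserial_scores(
                    r, t, (W[:, d] - m) / s, cat)))
                m0, s0 = W[:, d].mean(), W[:, d].std()
                S_rho = (Sfun(rho + h, tau, m0, s0) - Sfun(rho - h, tau, m0, s0)) / (2 * h)
                dtau = np.zeros(len(tau))
                for k in range(len(tau)):
                    e = np.zeros(len(tau)); e[k] = h
                    dtau[k] = (Sfun(rho, tau + e, m0, s0) - Sfun(rho, tau - e, m0, s0)) / (2 * h)
                hm = h * max(1.0, abs(m0)); hs = h * s0
                S_m = (Sfun(rho, tau, m0 + hm, s0) - Sfun(rho, tau, m0 - hm, s0)) / (2 * hm)
                S_s = (Sfun(rho, tau, m0, s0 + hs) - Sfun(rho, tau, m0, s0 - hs)) / (2 * hs)
                base = psi_tau[i][Xr[:, i], :]
                psi_m = W[:, d] - m0
                psi_s = ((W[:, d] - m0) ** 2 - s0**2) / (2 * s0)
                col = sc + base @ dtau + S_m * psi_m + S_s * psi_s
                labels.append(("corr_all", items[i], covariate_names[d]))
                cols.append(-col / S_rho)
                moments = np.append(moments, rho)
        for a in range(nv):
            for b in range(a + 1, nv):
                r = float(np.mean(wz[:, a] * wz[:, b]))
                labels.append(("corr_all", covariate_names[a], covariate_names[b]))
                cols.append(wz[:, a] * wz[:, b] - r * (wz[:, a] ** 2 + wz[:, b] ** 2) / 2)
                moments = np.append(moments, r)
        # assemble full correlation matrix over items + covariates
        full = np.eye(p + nv)
        full[:p, :p] = corr_mats["all"]
        full[:p, p:] = rho_iv
        full[p:, :p] = rho_iv.T
        cc = np.corrcoef(wz.T) if nv > 1 else np.ones((1, 1))
        full[p:, p:] = cc
        corr_mats["all"] = full

    # ---- asymptotic covariance -----------------------------------------
    if compute_acov:
        Psi = np.column_stack(cols)
        Psi = Psi - Psi.mean(axis=0)
        Gamma = Psi.T @ Psi / N
    else:
        Gamma = np.zeros((len(labels), len(labels)))

    var_names = items + covariate_names
    corr = {k: pd.DataFrame(v, index=var_names[: v.shape[0]],
                            columns=var_names[: v.shape[0]])
            for k, v in corr_mats.items()}
    rmsea_df = pd.DataFrame(np.maximum.reduce(list(rmsea_frames.values())),
                            index=items, columns=items) if rmsea_frames else None

    return Stage1Result(
        design=design, item_names=items, covariate_names=covariate_names,
        thresholds=thresholds, n_categories=Ks, corr=corr,
        foc_means=foc_means, foc_sds=foc_sds,
        pair_rmsea=rmsea_df, flagged_pairs=flagged,
        moments=moments, moment_labels=labels, acov=Gamma,
        n_total=N, n_per_group={"ref": n_ref, "foc": n_foc} if design == "multigroup"
        else {"all": N},
        boundary_pairs=boundary,
    )


# ---------------------------------------------------------------------------
# bootstrap cross-check for the asymptotic covariance


def bootstrap_acov(data: OrdinalDataset, design: str = "multigroup",
                   covariate_names: list[str] | None = None,
                   n_boot: int = 200, seed: int = 0) -> np.ndarray:
    """Nonparametric bootstrap estimate of Gamma (resampling within groups)."""
    rng = np.random.default_rng(seed)
    N = data.n_respondents
    reps = []
    g = data.group.to_numpy() if data.group is not None else None
    for _ in range(n_boot):
        if design == "multigroup":
            idx = np.concatenate([
                rng.choice(np.where(g == lev)[0], size=(g == lev).sum(), replace=True)
                for lev in np.unique(g)])
        else:
            idx = rng.integers(0, N, size=N)
        sub = OrdinalDataset(
            responses=data.responses.iloc[idx].reset_index(drop=True),
            group=None if g is None else pd.Series(g[idx], name="group"),
            covariates=None if data.covariates is None
            else data.covariates.iloc[idx].reset_index(drop=True),
        )
        r = run_stage1(sub, design=design, covariate_names=covariate_names,
                       compute_acov=False)
        reps.append(r.moments)
    S = np.cov(np.asarray(reps).T, ddof=1)
    return N * S
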