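"""Common-factor models with mean structure, fitted to Stage 1 moments.

Estimation is diagonally weighted least squares (DWLS): the discrepancy
(s - sigma(theta))' W (s - sigma(theta)) is minimized with W the inverse
diagonal of the asymptotic covariance of the estimated moments.  Overall
fit is judged by the weighted least squares (WLS) chi-square -- Browne's
residual-based statistic using the full asymptotic covariance matrix --
which is asymptotically chi-square distributed at the DWLS estimates.
Robust (sandwich) standard errors use the same full matrix.

Two model families cover the item-bias designs:

* :class:`MultigroupFactorModel` -- one factor per group, two groups, with
  optional cross-group equality of loadings and intercepts and selected
  focal-group parameters set free (partial invariance);
* :class:`RestrictedFactorModel` -- a single-group model with one or two
  correlated factors and optional exogenous violator variables that
  correlate with the factors and may have direct effects on items.

Identification: reference-group (or single-group) underlying variables are
standardized in Stage 1, so reference intercepts are 0 and reference
residual variances are determined by the unit diagonal; factor mean and
variance are fixed to 0/1 in the reference (or only) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import brentq, least_squares
from scipy.stats import chi2, ncx2, norm

from .stage1 import Stage1Result

__all__ = [
    "MultigroupFactorModel", "RestrictedFactorModel", "FitResult",
    "count_df", "fit_dwls", "rmsea_with_ci", "chisq_diff_test",
]


# ---------------------------------------------------------------------------
# model specifications


@dataclass(frozen=True)
class MultigroupFactorModel:
    """Two-group one-factor model for ordinal-item underlying variables.

    ``constrained=False`` is the Measurement Model: all loadings, focal
    intercepts and focal residual variances free per group, factor mean 0
    and variance 1 in both groups.  ``constrained=True`` is the
    No-Item-Bias / Final family: loadings and intercepts equal across
    groups except for the listed freed items; focal factor mean and
    variance free.
    """

    items: tuple[str, ...]
    constrained: bool = False
    free_focal_intercepts: tuple[str, ...] = ()
    free_focal_loadings: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = (set(self.free_focal_intercepts) | set(self.free_focal_loadings)) \
            - set(self.items)
        if unknown:
            raise ValueError(f"freed parameters reference unknown items: {unknown}")

    # -- bookkeeping ----------------------------------------------------
    @property
    def n_groups(self) -> int:
        return 2

    def param_names(self) -> list[str]:
        p = list(self.items)
        if not self.constrained:
            return ([f"lambda_ref[{i}]" for i in p]
                    + [f"lambda_foc[{i}]" for i in p]
                    + [f"nu_foc[{i}]" for i in p]
                    + [f"theta_foc[{i}]" for i in p])
        return ([f"lambda[{i}]" for i in p]
                + [f"theta_foc[{i}]" for i in p]
                + ["kappa_foc", "phi_foc"]
                + [f"nu_foc[{i}]" for i in self.free_focal_intercepts]
                + [f"lambda_foc[{i}]" for i in self.free_focal_loadings])

    def moment_labels(self) -> list[tuple]:
        p = list(self.items)
        pairs = [(p[i], p[j]) for i in range(len(p)) for j in range(i + 1, len(p))]
        return ([("corr_ref", a, b) for a, b in pairs]
                + [("mean_foc", i) for i in p]
                + [("sd_foc", i) for i in p]
                + [("corr_foc", a, b) for a, b in pairs])

    def count_df(self) -> int:
        """Formal df: per-group means + (co)variances minus free parameters
        (intercepts and residual variances counted per group as in the
        standard multigroup parameterization)."""
        p = len(self.items)
        moments = 2 * (p + p * (p + 1) // 2)
        if not self.constrained:
            free = 2 * 3 * p  # lambda, nu, theta per group
        else:
            free = (p + len(self.free_focal_loadings)   # loadings
                    + p + len(self.free_focal_intercepts)  # intercepts
                    + 2 * p                               # residual variances
                    + 2)                                  # focal kappa, phi
        df = moments - free
        if df < 0:
            raise ValueError("over-parameterized model (negative df)")
        return df

    # -- moments ---------------------------------------------------------
    def _unpack(self, th: np.ndarray):
        p = len(self.items)
        if not self.constrained:
            lam_r = th[:p]
            lam_f = th[p:2 * p]
            nu_f = th[2 * p:3 * p]
            theta_f = th[3 * p:4 * p]
            kappa, phi = 0.0, 1.0
        else:
            lam_r = th[:p].copy()
            theta_f = th[p:2 * p]
            kappa, phi = th[2 * p], th[2 * p + 1]
            nu_f = np.zeros(p)
            lam_f = lam_r.copy()
            k = 2 * p + 2
            for it in self.free_focal_intercepts:
                nu_f[self.items.index(it)] = th[k]; k += 1
            for it in self.free_focal_loadings:
                lam_f[self.items.index(it)] = th[k]; k += 1
        return lam_r, lam_f, nu_f, theta_f, kappa, phi

    def implied(self, th: np.ndarray) -> np.ndarray:
        lam_r, lam_f, nu_f, theta_f, kappa, phi = self._unpack(th)
        p = len(self.items)
        iu = np.triu_indices(p, 1)
        ref = np.outer(lam_r, lam_r)[iu]
        mu = nu_f + lam_f * kappa
        Sig = phi * np.outer(lam_f, lam_f) + np.diag(theta_f)
        sd = np.sqrt(np.clip(np.diag(Sig), 1e-10, None))
        cf = (Sig / np.outer(sd, sd))[iu]
        return np.concatenate([ref, mu, sd, cf])

    def start(self, stage1: Stage1Result, warm: dict | None = None) -> np.ndarray:
        p = len(self.items)
        defaults: dict[str, float] = {}
        for i, it in enumerate(self.items):
            defaults[f"lambda[{it}]"] = 0.7
            defaults[f"lambda_ref[{it}]"] = 0.7
            defaults[f"lambda_foc[{it}]"] = 0.7
            defaults[f"nu_foc[{it}]"] = float(stage1.foc_means[i])
            defaults[f"theta_foc[{it}]"] = 0.51
        defaults["kappa_foc"] = 0.0
        defaults["phi_foc"] = 1.0
        src = dict(defaults)
        if warm:
            src.update({k: v for k, v in warm.items() if k in set(self.param_names())
                        or k.startswith("lambda[")})
            # a shared loading can seed a freed focal loading and vice versa
            for it in self.free_focal_loadings:
                src.setdefault(f"lambda_foc[{it}]", warm.get(f"lambda[{it}]", 0.7))
        return np.array([src.get(nm, defaults.get(nm, 0.0)) for nm in self.param_names()])

    def bounds(self) -> list[tuple[float, float]]:
        b = []
        for nm in self.param_names():
            if nm.startswith("theta") or nm.startswith("phi"):
                b.append((1e-3, 25.0))
            elif nm.startswith("lambda"):
                b.append((-3.0, 3.0))
            else:
                b.append((-5.0, 5.0))
        return b


@dataclass(frozen=True)
class RestrictedFactorModel:
    """Single-group factor model with exogenous violators (RFA / MIMIC).

    Items load on their assigned factor (simple structure); factors are
    standardized with a free inter-factor correlation; violators are
    standardized observed variables that correlate freely with the factors
    and each other.  Uniform item bias appears as a free direct
    violator->item effect.
    """

    items: tuple[str, ...]
    item_factor: tuple[int, ...]
    n_factors: int = 2
    violators: tuple[str, ...] = ()
    free_direct: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if len(self.item_factor) != len(self.items):
            raise ValueError("item_factor must give a factor index per item")
        for it, v in self.free_direct:
            if it not in self.items or v not in self.violators:
                raise ValueError(f"direct effect ({it}, {v}) references unknown variable")

    @property
    def n_groups(self) -> int:
        return 1

    def param_names(self) -> list[str]:
        nm = [f"lambda[{i}]" for i in self.items]
        if self.n_factors == 2:
            nm.append("factor_corr")
        nm += [f"vf_corr[{v},{f}]" for v in self.violators for f in range(self.n_factors)]
        nv = len(self.violators)
        nm += [f"vv_corr[{self.violators[a]},{self.violators[b]}]"
               for a in range(nv) for b in range(a + 1, nv)]
        nm += [f"direct[{i},{v}]" for i, v in self.free_direct]
        return nm

    def moment_labels(self) -> list[tuple]:
        obs = list(self.items) + list(self.violators)
        p = len(self.items)
        out = [("corr_all", self.items[i], self.items[j])
               for i in range(p) for j in range(i + 1, p)]
        out += [("corr_all", self.items[i], v) for v in self.violators for i in range(p)]
        nv = len(self.violators)
        out += [("corr_all", self.violators[a], self.violators[b])
                for a in range(nv) for b in range(a + 1, nv)]
        return out

    def count_df(self) -> int:
        p, nv, nf = len(self.items), len(self.violators), self.n_factors
        pobs = p + nv
        moments = pobs + pobs * (pobs + 1) // 2
        free = 3 * p  # lambda, nu, theta per item
        free += 1 if nf == 2 else 0
        free += 2 * nv + nv * nf + nv * (nv - 1) // 2  # violator means/vars/corrs
        free += len(self.free_direct)
        df = moments - free
        if df < 0:
            raise ValueError("over-parameterized model (negative df)")
        return df

    def _unpack(self, th: np.ndarray):
        p, nv, nf = len(self.items), len(self.violators), self.n_factors
        k = 0
        lam = th[k:k + p]; k += p
        Pff = np.eye(nf)
        if nf == 2:
            Pff[0, 1] = Pff[1, 0] = th[k]; k += 1
        Pvf = th[k:k + nv * nf].reshape(nv, nf); k += nv * nf
        Pvv = np.eye(nv)
        for a in range(nv):
            for b in range(a + 1, nv):
                Pvv[a, b] = Pvv[b, a] = th[k]; k += 1
        D = np.zeros((p, nv))
        for it, v in self.free_direct:
            D[self.items.index(it), self.violators.index(v)] = th[k]; k += 1
        return lam, Pff, Pvf, Pvv, D

    def implied(self, th: np.ndarray) -> np.ndarray:
        lam, Pff, Pvf, Pvv, D = self._unpack(th)
        p, nv = len(self.items), len(self.violators)
        L = np.zeros((p, self.n_factors))
        L[np.arange(p), list(self.item_factor)] = lam
        Syy = L @ Pff @ L.T + L @ Pvf.T @ D.T + D @ Pvf @ L.T + D @ Pvv @ D.T
        out = [Syy[np.triu_indices(p, 1)]]
        if nv:
            Syv = L @ Pvf.T + D @ Pvv  # (p, nv)
            out.append(Syv.T.ravel())  # grouped by violator, matching labels
            out.append(Pvv[np.triu_indices(nv, 1)])
        return np.concatenate(out)

    def start(self, stage1: Stage1Result, warm: dict | None = None) -> np.ndarray:
        C = stage1.corr["all"]
        defaults: dict[str, float] = {f"lambda[{i}]": 0.7 for i in self.items}
        defaults["factor_corr"] = 0.5
        for v in self.violators:
            for f in range(self.n_factors):
                sub = [C.loc[i, v] for i, fi in zip(self.items, self.item_factor) if fi == f]
                defaults[f"vf_corr[{v},{f}]"] = float(np.clip(np.mean(sub) / 0.7, -0.9, 0.9))
        nv = len(self.violators)
        for a in range(nv):
            for b in range(a + 1, nv):
                defaults[f"vv_corr[{self.violators[a]},{self.violators[b]}]"] = float(
                    C.loc[self.violators[a], self.violators[b]])
        src = dict(defaults)
        if warm:
            src.update({k: v for k, v in warm.items()})
        return np.array([src.get(nm, 0.0) for nm in self.param_names()])

    def bounds(self) -> list[tuple[float, float]]:
        b = []
        for nm in self.param_names():
            if nm.startswith(("factor_corr", "vf_corr", "vv_corr")):
                b.append((-0.999, 0.999))
            else:
                b.append((-3.0, 3.0))
        return b


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    model: object
    estimates: dict[str, float]
    robust_ses: dict[str, float]
    chisq_wls: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    converged: bool
    n_total: int
    n_groups: int
    discrepancy: float
    theta: np.ndarray = field(repr=False, default=None)
    message: str = ""

    def z(self, name: str) -> float:
        return self.estimates[name] / self.robust_ses[name]

    def param_p(self, name: str) -> float:
        return 2.0 * norm.sf(abs(self.z(name)))

    def to_json_dict(self) -> dict:
        return {
            "chisq": self.chisq_wls, "df": self.df, "p_value": self.p_value,
            "rmsea": self.rmsea, "rmsea_ci": list(self.rmsea_ci),
            "converged": self.converged, "n_total": self.n_total,
            "parameters": [
                {"name": k, "estimate": v, "robust_se": self.robust_ses.get(k),
                 "z": (v / self.robust_ses[k]) if self.robust_ses.get(k) else None}
                for k, v in self.estimates.items()
            ],
        }


def count_df(model) -> int:
    """Degrees of freedom: modeled moments minus free parameter classes."""
    return model.count_df()


def _psd_solve(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve G X = B for symmetric positive definite G, ridging if needed."""
    try:
        c = cho_factor(G, lower=True)
        return cho_solve(c, B)
    except np.linalg.LinAlgError:
        lam = 1e-8 * float(np.mean(np.diag(G)))
        for _ in range(12):
            try:
                c = cho_factor(G + lam * np.eye(G.shape[0]), lower=True)
                return cho_solve(c, B)
            except np.linalg.LinAlgError:
                lam *= 10.0
        raise


def fit_dwls(model, stage1: Stage1Result, start: np.ndarray | None = None,
             warm: dict | None = None, compute_se: bool = True) -> FitResult:
    """Fit a model to Stage 1 moments by diagonally weighted least squares."""
    labels = model.moment_labels()
    idx = stage1.index_of(labels)
    s = stage1.moments[idx]
    Gamma = stage1.acov[np.ix_(idx, idx)]
    w = Gamma.diagonal().copy()
    w[w <= 1e-10] = 1e-10
    N = stage1.n_total

    sw = np.sqrt(w)

    def resid(th):
        return (s - model.implied(th)) / sw

    x0 = start if start is not None else model.start(stage1, warm=warm)
    lo_b, hi_b = map(np.asarray, zip(*model.bounds()))
    x0 = np.clip(x0, lo_b + 1e-10, hi_b - 1e-10)
    res = least_squares(resid, x0, bounds=(lo_b, hi_b), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-10, max_nfev=2000)
    th = res.x
    names = model.param_names()
    df = model.count_df()

    d = s - model.implied(th)
    Delta = -res.jac * sw[:, None]  # (M, q): d(implied)/d(theta)
    res_fun = float(2.0 * res.cost)
    M, q = Delta.shape
    # Browne residual-based WLS chi-square (asymptotically chi-square at
    # any consistent estimate, here the DWLS solution)
    Gi_d = _psd_solve(Gamma, d)
    Gi_D = _psd_solve(Gamma, Delta)
    A = Delta.T @ Gi_D  # (q, q)
    b = Delta.T @ Gi_d
    try:
        corr_term = float(b @ np.linalg.solve(A, b))
    except np.linalg.LinAlgError:
        corr_term = float(b @ np.linalg.lstsq(A, b, rcond=None)[0])
    chisq = (N - 1) * max(float(d @ Gi_d) - corr_term, 0.0)
    p_value = float(chi2.sf(chisq, df)) if df > 0 else 1.0
    rmsea, lo, hi = rmsea_with_ci(chisq, df, N, model.n_groups) if df > 0 \
        else (0.0, 0.0, 0.0)

    ses = {}
    if compute_se:
        Wd = 1.0 / w
        DtW = (Delta * Wd[:, None]).T  # q x M
        Abread = DtW @ Delta
        try:
            Abi = np.linalg.inv(Abread)
        except np.linalg.LinAlgError:
            Abi = np.linalg.pinv(Abread)
        meat = DtW @ Gamma @ DtW.T
        V = Abi @ meat @ Abi / N
        ses = {nm: float(np.sqrt(max(v, 0.0))) for nm, v in zip(names, np.diag(V))}

    return FitResult(
        model=model,
        estimates=dict(zip(names, th)),
        robust_ses=ses,
        chisq_wls=float(chisq), df=df, p_value=p_value,
        rmsea=rmsea, rmsea_ci=(lo, hi),
        converged=bool(res.success), n_total=N, n_groups=model.n_groups,
        discrepancy=res_fun, theta=th, message=str(res.message),
    )


# ---------------------------------------------------------------------------
# fit statistics


def rmsea_with_ci(chisq: float, df: int, n_total: int, n_groups: int = 1,
                  level: float = 0.90) -> tuple[float, float, float]:
    """RMSEA with a confidence interval from the noncentral chi-square.

    rmsea = sqrt(G * max(0, chisq - df) / (df * N)); the interval inverts
    the noncentral chi-square distribution in its noncentrality parameter.
    """
    if df <= 0:
        raise ValueError("RMSEA undefined for df <= 0")
    if n_total <= 1:
        raise ValueError("need n_total > 1")
    val = np.sqrt(n_groups * max(0.0, chisq - df) / (df * n_total))
    a = (1.0 - level) / 2.0

    def nc_for(prob: float) -> float:
        # largest lambda with P(X_{df,lambda} <= chisq) >= prob
        if ncx2.cdf(chisq, df, 1e-10) < prob:
            return 0.0
        hi = max(chisq * 2.0, 10.0)
        f = lambda nc: ncx2.cdf(chisq, df, nc) - prob
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e7:
                break
        return brentq(f, 1e-10, hi, xtol=1e-8)

    lam_lo = nc_for(1.0 - a)  # 0.95 quantile -> lower bound
    lam_hi = nc_for(a)        # 0.05 quantile -> upper bound
    lo = np.sqrt(n_groups * lam_lo / (df * n_total))
    hi = np.sqrt(n_groups * lam_hi / (df * n_total))
    return float(val), float(lo), float(hi)


def chisq_diff_test(nested: FitResult, parent: FitResult) -> tuple[float, int, float, bool]:
    """Chi-square difference test for nested models fitted to the same data.

    Returns ``(diff, df_diff, p, warn)``; a negative difference (possible
    with DWLS point estimates) is reported with ``warn=True`` and p = 1.
    """
    if nested.df < parent.df:
        raise ValueError("nested model must have at least as many df as parent")
    diff = nested.chisq_wls - parent.chisq_wls
    df_diff = nested.df - parent.df
    if diff < 0:
        return float(diff), df_diff, 1.0, True
    if df_diff == 0:
        return float(diff), 0, 1.0, False
    return float(diff), df_diff, float(chi2.sf(diff, df_diff)), False
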