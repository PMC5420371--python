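"""Multigroup item-bias detection (reference vs focal group).

The four-step procedure:

1. *Measurement Model* -- a one-factor model per group with no cross-group
   constraints (factor mean 0, variance 1 in both groups); overall fit is
   judged by the RMSEA.
2. *No Item Bias Model* -- loadings and intercepts constrained equal
   across groups; the focal factor mean and variance become free.  A
   significant chi-square difference against the Measurement Model
   indicates item bias.  Residual variances stay free per group: their
   differences are not treated as bias and do not affect latent means.
3. *Iterative bias search* -- each remaining equality constraint is freed
   one at a time; the candidate with the largest fit improvement is
   adopted if its 1-df chi-square difference is significant (default
   p < .001).  Freed intercepts flag uniform bias, freed loadings
   nonuniform bias.
4. *True differences* -- the focal factor mean of the Final Model gives
   the bias-adjusted group difference (Cohen's d); the No-Item-Bias Model
   gives the unadjusted one.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, norm

from .generate import OrdinalDataset
from .report import DifFinding, DifReport, TrailEntry
from .sem import FitResult, MultigroupFactorModel, chisq_diff_test, fit_dwls
from .stage1 import Stage1Result, run_stage1

ALPHA_DEFAULT = 1e-3
IMPORTANCE_D = 0.2


def fit_measurement_model(stage1: Stage1Result, compute_se: bool = False) -> FitResult:
    model = MultigroupFactorModel(tuple(stage1.item_names), constrained=False)
    return fit_dwls(model, stage1, compute_se=compute_se)


def fit_no_bias_model(stage1: Stage1Result, warm: dict | None = None,
                      compute_se: bool = False) -> FitResult:
    model = MultigroupFactorModel(tuple(stage1.item_names), constrained=True)
    return fit_dwls(model, stage1, warm=warm, compute_se=compute_se)


# ---------------------------------------------------------------------------
# effect sizes


def effect_size_uniform(nu_ref: float, nu_foc: float, sd_pooled: float) -> float:
    """Uniform-bias size: intercept difference over the pooled item SD.

    Positive values mean the focal group endorses the item more highly at
    equal trait level.  Benchmarks 0.2 / 0.5 / 0.8 (small / medium / large).
    """
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be positive")
    return (nu_foc - nu_ref) / sd_pooled


def effect_size_nonuniform(lambda_ref: float, lambda_foc: float,
                           kappa_ref: float, kappa_foc: float,
                           sd_pooled: float) -> float:
    """Nonuniform-bias size: loading difference times latent mean
    difference, over the pooled item SD (zero when latent means are equal)."""
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be positive")
    return (lambda_foc - lambda_ref) * (kappa_foc - kappa_ref) / sd_pooled


def _pooled_item_sd(fit: FitResult, item: str) -> float:
    """Model-implied pooled underlying SD: sqrt((var_ref + var_foc)/2).

    The reference-group underlying variance is 1 by identification."""
    est = fit.estimates
    lam_f = est.get(f"lambda_foc[{item}]", est.get(f"lambda[{item}]",
                    est.get(f"lambda_ref[{item}]")))
    phi = est.get("phi_foc", 1.0)
    var_foc = phi * lam_f**2 + est[f"theta_foc[{item}]"]
    return float(np.sqrt((1.0 + var_foc) / 2.0))


def true_difference(final: FitResult, no_bias: FitResult) -> dict:
    """Latent group difference d = kappa_foc / pooled factor SD, with its
    p-value, from the Final (adjusted) and No-Item-Bias (unadjusted) fits."""
    out = {}
    for key, fit in (("adjusted", final), ("unadjusted", no_bias)):
        kappa = fit.estimates["kappa_foc"]
        phi = fit.estimates["phi_foc"]
        sd = np.sqrt((1.0 + phi) / 2.0)
        se = fit.robust_ses.get("kappa_foc")
        p = 2.0 * norm.sf(abs(kappa / se)) if se else np.nan
        out[key] = (float(kappa / sd), float(p))
    return out


# ---------------------------------------------------------------------------
# the iterative search


def iterative_bias_search(stage1: Stage1Result, no_bias: FitResult,
                          measurement: FitResult, alpha: float = ALPHA_DEFAULT,
                          max_steps: int | None = None):
    """Greedy forward search over cross-group equality constraints.

    Returns ``(findings, final_fit, log)``.  Each step frees the single
    loading or intercept whose release improves the WLS chi-square most,
    keeps it if the 1-df difference test is significant at ``alpha``, and
    stops otherwise.  A freed parameter stays free (no backward step).
    Residual variances are never candidates.
    """
    items = stage1.item_names
    log: list[str] = []
    findings: list[DifFinding] = []
    current = no_bias
    freed_nu: list[str] = list(no_bias.model.free_focal_intercepts)
    freed_lam: list[str] = list(no_bias.model.free_focal_loadings)
    max_steps = max_steps if max_steps is not None else 2 * len(items)

    d, dd, p, warn = chisq_diff_test(no_bias, measurement)
    log.append(f"No Item Bias vs Measurement: chisq_diff={d:.2f} df={dd} p={p:.4g}")
    if p >= alpha:
        log.append("no indication of item bias; search not started")
        return findings, current, log

    step = 0
    while step < max_steps:
        step += 1
        candidates = []
        for it in items:
            if it not in freed_nu:
                candidates.append((it, "uniform"))
            if it not in freed_lam:
                candidates.append((it, "nonuniform"))
        if not candidates:
            break
        best = None
        for it, kind in candidates:
            model = MultigroupFactorModel(
                tuple(items), constrained=True,
                free_focal_intercepts=tuple(freed_nu + ([it] if kind == "uniform" else [])),
                free_focal_loadings=tuple(freed_lam + ([it] if kind == "nonuniform" else [])),
            )
            try:
                fit = fit_dwls(model, stage1, warm=current.estimates, compute_se=False)
            except Exception as exc:  # pragma: no cover - defensive
                log.append(f"candidate ({it}, {kind}) failed: {exc}")
                continue
            if not fit.converged:
                log.append(f"candidate ({it}, {kind}) did not converge; skipped")
                continue
            improvement = current.chisq_wls - fit.chisq_wls
            # deterministic tie-break: larger improvement, then lower item
            # index, then intercept before loading
            key = (improvement, -items.index(it), kind == "uniform")
            if best is None or key > best[0]:
                best = (key, it, kind, fit, improvement)
        if best is None:
            log.append("no converging candidates remain; search stopped")
            break
        _, it, kind, fit, improvement = best
        diff = max(improvement, 0.0)
        p_diff = float(chi2.sf(diff, 1)) if improvement >= 0 else 1.0
        if improvement < 0:
            log.append(f"best candidate ({it}, {kind}) decreased fit "
                       f"(chisq_diff={improvement:.2f}); non-monotonicity noted")
        log.append(f"step {step}: best candidate ({it}, {kind}) "
                   f"chisq_diff={improvement:.2f} p={p_diff:.4g}")
        if p_diff >= alpha:
            log.append("no further significant constraint; search stopped")
            break
        findings.append(DifFinding(
            item=it, violator="group", type=kind, chisq_diff=float(improvement),
            df_diff=1, p=p_diff, effect_size=np.nan, important=False,
            step_index=step,
        ))
        (freed_nu if kind == "uniform" else freed_lam).append(it)
        current = fit
        d, dd, p, warn = chisq_diff_test(current, measurement)
        if p >= alpha:
            log.append(f"current model now fits equivalently to the Measurement "
                       f"Model (chisq_diff={d:.2f} df={dd} p={p:.4g}); "
                       "candidate scan continues")
    return findings, current, log


# ---------------------------------------------------------------------------
# the full procedure


def run_multigroup(data: OrdinalDataset, alpha: float = ALPHA_DEFAULT,
                   importance_d: float = IMPORTANCE_D,
                   stage1_result: Stage1Result | None = None) -> DifReport:
    """Run the complete multigroup item-bias procedure on a dataset."""
    s1 = stage1_result if stage1_result is not None \
        else run_stage1(data, design="multigroup")
    measurement = fit_measurement_model(s1)
    no_bias = fit_no_bias_model(s1, warm=measurement.estimates)
    findings, final, log = iterative_bias_search(s1, no_bias, measurement, alpha=alpha)

    # refit final and no-bias with robust SEs for effect sizes / latent d
    final = fit_dwls(final.model, s1, start=final.theta, compute_se=True)
    no_bias_se = fit_dwls(no_bias.model, s1, start=no_bias.theta, compute_se=True)

    kappa = final.estimates.get("kappa_foc", 0.0)
    for f in findings:
        sd = _pooled_item_sd(final, f.item)
        if f.type == "uniform":
            f.effect_size = effect_size_uniform(0.0, final.estimates[f"nu_foc[{f.item}]"], sd)
        else:
            lam_shared = final.estimates[f"lambda[{f.item}]"]
            f.effect_size = effect_size_nonuniform(
                lam_shared, final.estimates[f"lambda_foc[{f.item}]"], 0.0, kappa, sd)
        f.important = bool(abs(f.effect_size) > importance_d and f.p < alpha)

    td = true_difference(final, no_bias_se)

    trail = [TrailEntry("Measurement Model", measurement)]
    d, dd, p, _ = chisq_diff_test(no_bias_se, measurement)
    trail.append(TrailEntry("No Item Bias Model", no_bias_se,
                            "Measurement Model", d, dd, p))
    d, dd, p, _ = chisq_diff_test(final, measurement)
    trail.append(TrailEntry("Final Model", final, "Measurement Model", d, dd, p))

    return DifReport(
        procedure="multigroup",
        findings=findings, model_trail=trail,
        true_difference_adjusted=td["adjusted"],
        true_difference_unadjusted=td["unadjusted"],
        flagged_pairs=s1.flagged_pairs,
        decisions_log=log,
        notes=(["Stage 1 flagged item pairs for bivariate non-normality; "
                "consider eliminating the offending variable(s)."]
               if s1.flagged_pairs else []),
    )
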