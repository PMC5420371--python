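"""Simulation studies: calibration, power, bias absorption, recovery.

These drive the acceptance tests and the acceptance script.  Every study
is deterministic given its base seed; replicate seeds are derived by
offset and stay below 2**31.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .generate import DifDef, make_hads_like_spec, simulate
from .multidim import run_multidim
from .multigroup import run_multigroup
from .stage1 import run_stage1

_SEED_MOD = 2**31 - 1


def _dseed(base: int, offset: int) -> int:
    return int((base + offset) % _SEED_MOD)


# ---------------------------------------------------------------------------
# type-I error


def type1_multigroup(n_reps: int = 200, n_per_group: int = 1000,
                     seed: int = 0) -> dict:
    """No-DIF two-group replicates: per-item false-positive rate of the
    multigroup search at alpha = .001."""
    spec = make_hads_like_spec("no_dif")
    false_items = 0
    flagged_reps = 0
    for r in range(n_reps):
        d = simulate(spec, n_per_group=n_per_group, seed=_dseed(seed, r))
        rep = run_multigroup(d)
        if rep.findings:
            flagged_reps += 1
            false_items += len(rep.findings)
    return {
        "per_item_fp_rate": false_items / (n_reps * 7),
        "familywise_rate": flagged_reps / n_reps,
        "n_reps": n_reps,
    }


def type1_multidim(n_reps: int = 100, n_total: int = 2000,
                   seed: int = 0) -> dict:
    """No-DIF one-group replicates (14 items, 2 violators): fraction of
    replicates in which the multidimensional search flags any item."""
    spec = make_hads_like_spec("two_factor_14")
    flagged_reps = 0
    for r in range(n_reps):
        d = simulate(spec, n_per_group=n_total, seed=_dseed(seed, 10_000 + r))
        rep = run_multidim(d, violators=("gender", "age"))
        if rep.findings:
            flagged_reps += 1
    return {
        "no_flag_rate": 1.0 - flagged_reps / n_reps,
        "familywise_rate": flagged_reps / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# power / localization


def power_multigroup(n_reps: int = 60, n_per_group: int = 1000,
                     dif_size: float = 0.5, seed: int = 0) -> dict:
    """Uniform DIF of ``dif_size`` SD on item3: fraction of replicates in
    which the multigroup search detects it and ranks it first."""
    spec = make_hads_like_spec("uniform_dif", dif_size=dif_size, dif_items=(2,))
    detected = localized = 0
    for r in range(n_reps):
        d = simulate(spec, n_per_group=n_per_group, seed=_dseed(seed, 20_000 + r))
        rep = run_multigroup(d)
        hits = [f for f in rep.findings if f.item == "item3"]
        if hits:
            detected += 1
        if rep.findings and rep.findings[0].item == "item3":
            localized += 1
    return {"detect_rate": detected / n_reps,
            "localize_rate": localized / n_reps, "n_reps": n_reps}


def power_multidim(n_reps: int = 40, n_total: int = 2000,
                   dif_size: float = 0.5, seed: int = 0) -> dict:
    """Uniform DIF of ``dif_size`` SD on item5 w.r.t. the (standardized)
    gender violator: detection/localization rate of the multidimensional
    search."""
    detected = localized = 0
    for r in range(n_reps):
        spec = make_hads_like_spec("two_factor_14")
        spec.dif_defs = [DifDef(item=4, violator="gender", kind="uniform",
                                size=dif_size)]
        d = simulate(spec, n_per_group=n_total, seed=_dseed(seed, 30_000 + r))
        rep = run_multidim(d, violators=("gender", "age"))
        hits = [f for f in rep.findings
                if f.item == "item5" and f.violator == "gender"]
        if hits:
            detected += 1
        if rep.findings and rep.findings[0].item == "item5" \
                and rep.findings[0].violator == "gender":
            localized += 1
    return {"detect_rate": detected / n_reps,
            "localize_rate": localized / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# bias absorption


def bias_absorption(n_reps: int = 3, n_total: int = 2500,
                    seed: int = 0) -> dict:
    """Age truly unrelated to factor 2, but the two age-DIF-carrying
    factor-2 items bias the unadjusted association.  Returns per-replicate
    unadjusted/adjusted age-factor2 associations with p-values.

    Two of seven factor-2 items carry the bias: with more contaminated
    items the biased/unbiased partition becomes statistically
    near-equivalent and the greedy search can select the complementary
    (all-clean-items-freed) solution."""
    rows = []
    for r in range(n_reps):
        spec = make_hads_like_spec("two_factor_14")
        spec.violators[1].factor_corr = (-0.25, 0.0)
        spec.dif_defs = [DifDef(item=i, violator="age", kind="uniform",
                                size=-0.4) for i in (8, 10)]
        d = simulate(spec, n_per_group=n_total, seed=_dseed(seed, 40_000 + r))
        rep = run_multidim(d, violators=("gender", "age"))
        entry = {}
        for a in rep.associations:
            if a.pair == ("age", "factor2"):
                entry[a.context] = (a.r, a.p)
        rows.append(entry)
    return {
        "replicates": rows,
        "unadjusted_signif": sum(e["unadjusted"][1] < 0.05 for e in rows),
        "adjusted_covers_zero": sum(e["adjusted"][1] >= 0.05 for e in rows),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# parameter recovery


def recovery(n: int = 5000, seed: int = 0, n_reps_mg: int = 20,
             n_reps_md: int = 10) -> dict:
    """Recovery errors of replicate-averaged estimates on correctly
    specified one- and two-factor generators at sample size ``n``.

    Individual parameters (notably phi) have sampling SDs above 0.05 even
    at n=5000, so recovery-to-0.05 is asserted on the mean estimate over
    replicates: it checks unbiasedness/consistency, not a single draw.
    """
    from .multidim import fit_md_measurement
    from .multigroup import fit_no_bias_model

    # one-factor, two groups, focal kappa/phi nontrivial
    spec = make_hads_like_spec("no_dif")
    spec.factor_means = np.array([[0.0], [0.3]])
    spec.factor_sds = np.array([[1.0], [np.sqrt(1.2)]])
    lams, taus, nus, kaps, phis = [], [], [], [], []
    for r in range(n_reps_mg):
        d = simulate(spec, n_per_group=n, seed=_dseed(seed, 50_000 + r))
        s1 = run_stage1(d, design="multigroup")
        fit = fit_no_bias_model(s1)
        lam = np.array([fit.estimates[f"lambda[{it}]"]
                        for it in s1.item_names])
        lams.append(lam)
        taus.append(np.vstack(s1.thresholds))
        # generator nu = 0; model-implied focal means are nu + lambda*kappa,
        # so the focal-mean residual estimates nu
        nus.append(s1.foc_means - lam * fit.estimates["kappa_foc"])
        kaps.append(fit.estimates["kappa_foc"])
        phis.append(fit.estimates["phi_foc"])
    out = {
        "mg_lambda_max_err": float(np.abs(np.mean(lams, axis=0)
                                          - spec.loadings).max()),
        "mg_nu_max_err": float(np.abs(np.mean(nus, axis=0)).max()),
        "mg_tau_max_err": float(np.abs(np.mean(taus, axis=0)
                                       - spec.thresholds).max()),
        "mg_kappa_err": float(abs(np.mean(kaps) - 0.3)),
        "mg_phi_err": float(abs(np.mean(phis) - 1.2)),
    }

    # two-factor, one group
    spec2 = make_hads_like_spec("two_factor_14")
    spec2.violators = []
    lams2, taus2, fcs = [], [], []
    for r in range(n_reps_md):
        d2 = simulate(spec2, n_per_group=n, seed=_dseed(seed, 60_000 + r))
        s2 = run_stage1(d2, design="single")
        fit2 = fit_md_measurement(s2)
        lams2.append([fit2.estimates[f"lambda[{it}]"]
                      for it in s2.item_names])
        taus2.append(np.vstack(s2.thresholds))
        fcs.append(fit2.estimates["factor_corr"])
    out.update({
        "md_lambda_max_err": float(np.abs(np.mean(lams2, axis=0)
                                          - spec2.loadings).max()),
        "md_tau_max_err": float(np.abs(np.mean(taus2, axis=0)
                                       - spec2.thresholds).max()),
        "md_factor_corr_err": float(abs(np.mean(fcs) - 0.8)),
    })
    return out
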