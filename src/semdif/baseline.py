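"""Ordinal logistic regression baseline for item-bias detection.

For each item, a proportional-odds model regresses the item response on a
matching score (the rest score by default: the sum of the *other* items,
so the studied item does not contaminate its own matching variable) and
the candidate violator (group indicator or covariate).  A non-zero
violator effect at equal score level flags uniform bias.  The violator's
log-odds ratio is the effect size; |logOR| > 0.64 (roughly a "medium"
standardized difference) with p < .001 marks an important effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .generate import OrdinalDataset

ALPHA_DEFAULT = 1e-3
IMPORTANCE_LOGOR = 0.64


@dataclass
class BaselineFinding:
    item: str
    violator: str
    log_odds_ratio: float
    se: float
    p: float
    flagged: bool
    important: bool

    def as_dict(self) -> dict:
        return {"item": self.item, "violator": self.violator,
                "log_odds_ratio": self.log_odds_ratio, "se": self.se,
                "p": self.p, "flagged": self.flagged, "important": self.important}


def _violator_column(data: OrdinalDataset, violator: str) -> np.ndarray:
    if violator == "group":
        if data.group is None:
            raise ValueError("dataset has no group column")
        g = data.group.to_numpy()
        levels = np.unique(g)
        if len(levels) != 2:
            raise ValueError("group must take exactly two values")
        return (g == levels[1]).astype(float)
    if data.covariates is None or violator not in data.covariates.columns:
        raise ValueError(f"unknown violator {violator!r}")
    return data.covariates[violator].to_numpy(dtype=float)


def run_baseline(data: OrdinalDataset, violators: tuple[str, ...] = ("group",),
                 alpha: float = ALPHA_DEFAULT,
                 importance_logor: float = IMPORTANCE_LOGOR,
                 matching: str = "rest") -> list[BaselineFinding]:
    """Proportional-odds screen of every (item, violator) pair.

    ``matching`` is ``"rest"`` (sum of the other items, default) or
    ``"total"`` (sum including the studied item; kept for comparison, it
    is biased toward the studied item).
    """
    if matching not in ("rest", "total"):
        raise ValueError("matching must be 'rest' or 'total'")
    X = data.responses.to_numpy(dtype=float)
    total = X.sum(axis=1)
    out: list[BaselineFinding] = []
    for v in violators:
        w = _violator_column(data, v)
        if len(np.unique(w)) == 2:
            # binary: keep the 0/1 coding so logOR is the group odds ratio
            wz = (w - w.min()) / (w.max() - w.min())
        else:
            # continuous: per-SD so logOR is comparable across violators
            wz = (w - w.mean()) / w.std()
        for j, item in enumerate(data.item_names):
            score = total - X[:, j] if matching == "rest" else total
            sz = (score - score.mean()) / score.std()
            exog = pd.DataFrame({"score": sz, v: wz})
            endog = pd.Series(X[:, j]).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = OrderedModel(endog, exog, distr="logit")
                fit = model.fit(method="bfgs", disp=False, maxiter=200)
            beta = float(fit.params[v])
            se = float(fit.bse[v])
            p = float(fit.pvalues[v])
            flagged = p < alpha
            out.append(BaselineFinding(
                item=item, violator=v, log_odds_ratio=beta, se=se, p=p,
                flagged=flagged,
                important=bool(flagged and abs(beta) > importance_logor),
            ))
    return out


def baseline_frame(findings: list[BaselineFinding]) -> pd.DataFrame:
    cols = ["item", "violator", "log_odds_ratio", "se", "p", "flagged", "important"]
    return pd.DataFrame([f.as_dict() for f in findings], columns=cols)
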