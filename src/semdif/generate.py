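"""Synthetic ordinal item-response data from a graded common-factor model.

The generator emulates HADS-style questionnaires: 7- or 14-item scales with
four response categories per item, one or two correlated latent factors, an
optional binary grouping (reference vs focal), and observed "violator"
covariates (binary, like gender; continuous, like age) that may be
correlated with the factors.  Uniform bias is injected as an additive
violator effect on an item's underlying continuous response; nonuniform
bias as a violator-by-trait interaction (a loading shift).

Underlying response for item i of respondent j in group g:

    y_ij = nu_i + lambda_i * T_j + sum_d delta_d * V_dj [+ gamma_d * V_dj * T_j] + e_ij

with T_j ~ N(kappa_g, phi_g), e_ij ~ N(0, theta_i), discretized at the item
thresholds tau_i into categories 0..K-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm


@dataclass
class ViolatorDef:
    """An observed covariate with respect to which items may be biased."""

    name: str
    kind: str  # "binary" | "continuous"
    factor_corr: tuple[float, ...] = (0.0,)  # correlation with each factor
    prevalence: float = 0.5  # binary only
    mean: float = 0.0  # continuous only (reporting scale)
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"violator kind must be binary/continuous, got {self.kind!r}")


@dataclass
class DifDef:
    """One injected item bias: (item, violator, type, size).

    ``size`` is on the underlying-response scale, per SD of the violator
    (for the special violator ``"group"`` the raw 0/1 indicator is used, so
    the focal group's underlying mean shifts by exactly ``size``).
    """

    item: int
    violator: str  # a ViolatorDef name, or "group"
    kind: str  # "uniform" | "nonuniform"
    size: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "nonuniform"):
            raise ValueError(f"dif kind must be uniform/nonuniform, got {self.kind!r}")


@dataclass
class GeneratorSpec:
    """Population parameters for the graded common-factor generator."""

    n_items: int
    n_categories: int = 4
    loadings: np.ndarray | None = None  # (n_items,)
    intercepts: np.ndarray | None = None  # (n_items,)
    residual_sds: np.ndarray | None = None
    thresholds: np.ndarray | None = None  # (n_items, K-1), increasing
    item_factor: np.ndarray | None = None  # factor index per item
    n_factors: int = 1
    factor_corr: float = 0.0
    factor_means: np.ndarray | None = None  # (n_groups, n_factors)
    factor_sds: np.ndarray | None = None
    violators: list[ViolatorDef] = field(default_factory=list)
    dif_defs: list[DifDef] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        p, K = self.n_items, self.n_categories
        if self.loadings is None:
            self.loadings = np.full(p, 0.7)
        if self.intercepts is None:
            self.intercepts = np.zeros(p)
        if self.residual_sds is None:
            self.residual_sds = np.sqrt(1.0 - np.asarray(self.loadings) ** 2)
        if self.thresholds is None:
            base = norm.ppf(np.arange(1, K) / K)
            self.thresholds = np.tile(base, (p, 1))
        if self.item_factor is None:
            self.item_factor = np.zeros(p, dtype=int)
        if self.factor_means is None:
            self.factor_means = np.zeros((1, self.n_factors))
        if self.factor_sds is None:
            self.factor_sds = np.ones((1, self.n_factors))
        for name in ("loadings", "intercepts", "residual_sds", "thresholds",
                     "item_factor", "factor_means", "factor_sds"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.factor_means = np.atleast_2d(self.factor_means)
        self.factor_sds = np.atleast_2d(self.factor_sds)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("item thresholds must be strictly increasing")
        if np.any(self.residual_sds <= 0) or np.any(self.factor_sds <= 0):
            raise ValueError("residual and factor SDs must be positive")
        if not abs(self.factor_corr) < 1:
            raise ValueError("|factor_corr| must be < 1")
        names = {v.name for v in self.violators} | {"group"}
        for d in self.dif_defs:
            if not 0 <= d.item < self.n_items:
                raise ValueError(f"dif_def references unknown item {d.item}")
            if d.violator not in names:
                raise ValueError(f"dif_def references unknown violator {d.violator!r}")
        for v in self.violators:
            if len(v.factor_corr) != self.n_factors:
                raise ValueError(f"violator {v.name!r} needs {self.n_factors} factor correlations")

    @property
    def n_groups(self) -> int:
        return self.factor_means.shape[0]

    # -- provenance ------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["violators"] = [ViolatorDef(**v) if isinstance(v, dict) else v
                          for v in d.get("violators", [])]
        d["dif_defs"] = [DifDef(**v) if isinstance(v, dict) else v
                         for v in d.get("dif_defs", [])]
        return cls(**d)


@dataclass
class OrdinalDataset:
    """Respondents x items integer categories plus grouping/covariate columns."""

    responses: pd.DataFrame  # integer categories 0..K-1
    group: pd.Series | None = None  # binary labels (0 reference, 1 focal)
    covariates: pd.DataFrame | None = None
    latent: pd.DataFrame | None = None  # underlying continuous responses (debug)

    @property
    def item_names(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def to_frame(self) -> pd.DataFrame:
        parts = [self.responses]
        if self.group is not None:
            parts.append(self.group.rename("group"))
        if self.covariates is not None:
            parts.append(self.covariates)
        return pd.concat(parts, axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, items: list[str] | None = None,
                 group: str | None = "group",
                 covariates: list[str] | None = None) -> "OrdinalDataset":
        df = pd.read_csv(path)
        special = ([group] if group and group in df.columns else []) + (covariates or [])
        if items is None:
            items = [c for c in df.columns if c not in special]
        grp = df[group].astype(int) if group and group in df.columns else None
        cov = df[covariates] if covariates else None
        return cls(responses=df[items].astype(int), group=grp, covariates=cov)


# ---------------------------------------------------------------------------
# scenarios

_SCENARIOS = ("one_factor_7", "two_factor_14", "no_dif", "uniform_dif", "nonuniform_dif")


def make_hads_like_spec(scenario: str, dif_size: float = 0.5,
                        dif_items: tuple[int, ...] = (2,)) -> GeneratorSpec:
    """Canned generator specs mirroring a HADS-like study design.

    ``one_factor_7``: a single 7-item subscale, two groups of equal latent
    distribution.  ``two_factor_14``: both subscales, one population, factor
    correlation 0.8, binary and continuous violators.  ``no_dif`` /
    ``uniform_dif`` / ``nonuniform_dif``: the 7-item two-group design with
    no, intercept-type, or loading-type bias on ``dif_items``.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {', '.join(_SCENARIOS)}")
    # staggered loadings/thresholds typical of symptom scales
    lam7 = np.array([0.75, 0.65, 0.80, 0.70, 0.60, 0.72, 0.68])
    thr7 = np.array([norm.ppf(np.cumsum(pr)[:-1]) for pr in (
        [0.35, 0.30, 0.20, 0.15],) * 7])
    if scenario in ("one_factor_7", "no_dif", "uniform_dif", "nonuniform_dif"):
        difs: list[DifDef] = []
        if scenario == "uniform_dif":
            difs = [DifDef(item=i, violator="group", kind="uniform", size=dif_size)
                    for i in dif_items]
        elif scenario == "nonuniform_dif":
            difs = [DifDef(item=i, violator="group", kind="nonuniform", size=dif_size)
                    for i in dif_items]
        return GeneratorSpec(
            n_items=7, loadings=lam7, thresholds=thr7,
            factor_means=np.zeros((2, 1)), factor_sds=np.ones((2, 1)),
            dif_defs=difs,
        )
    # two_factor_14: one population, anxiety + depression, violators age/gender
    lam = np.concatenate([lam7, lam7[::-1]])
    thr = np.vstack([thr7, thr7])
    return GeneratorSpec(
        n_items=14, loadings=lam, thresholds=thr,
        item_factor=np.repeat([0, 1], 7), n_factors=2, factor_corr=0.8,
        factor_means=np.zeros((1, 2)), factor_sds=np.ones((1, 2)),
        violators=[
            ViolatorDef("gender", "binary", factor_corr=(-0.15, -0.05), prevalence=0.4),
            ViolatorDef("age", "continuous", factor_corr=(-0.25, 0.05), mean=50.0, sd=18.0),
        ],
    )


# ---------------------------------------------------------------------------
# simulation


def simulate(spec: GeneratorSpec, n_per_group: int, seed: int | None = None,
             return_latent: bool = False) -> OrdinalDataset:
    """Draw an :class:`OrdinalDataset` from the generator model.

    Deterministic for a fixed seed.  With ``return_latent`` the underlying
    continuous response matrix (before discretization) is attached, so that
    injected bias sizes can be verified directly.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    G, nf, p = spec.n_groups, spec.n_factors, spec.n_items
    nv = len(spec.violators)

    # joint latent layer: factors (standardized) + violator latents
    C = np.eye(nf + nv)
    if nf == 2:
        C[0, 1] = C[1, 0] = spec.factor_corr
    for d, v in enumerate(spec.violators):
        for f in range(nf):
            C[nf + d, f] = C[f, nf + d] = v.factor_corr[f]
    L = np.linalg.cholesky(C)

    blocks = []
    for g in range(G):
        n = n_per_group
        Z = rng.standard_normal((n, nf + nv)) @ L.T
        T = spec.factor_means[g] + spec.factor_sds[g] * Z[:, :nf]  # (n, nf)
        Vlat = Z[:, nf:]
        Vz = np.empty_like(Vlat)  # standardized / indicator scale for DIF terms
        Vobs = np.empty_like(Vlat)
        for d, v in enumerate(spec.violators):
            if v.kind == "binary":
                cut = norm.ppf(1.0 - v.prevalence)
                ind = (Vlat[:, d] > cut).astype(float)
                Vz[:, d] = (ind - v.prevalence) / np.sqrt(v.prevalence * (1 - v.prevalence))
                Vobs[:, d] = ind
            else:
                Vz[:, d] = Vlat[:, d]
                Vobs[:, d] = v.mean + v.sd * Vlat[:, d]

        Tit = T[:, spec.item_factor]  # trait relevant to each item, (n, p)
        Y = spec.intercepts + spec.loadings * Tit
        for dd in spec.dif_defs:
            if dd.violator == "group":
                vcol = np.full(n, float(g))
            else:
                vcol = Vz[:, [v.name for v in spec.violators].index(dd.violator)]
            if dd.kind == "uniform":
                Y[:, dd.item] += dd.size * vcol
            else:
                Y[:, dd.item] += dd.size * vcol * Tit[:, dd.item]
        Y += rng.standard_normal((n, p)) * spec.residual_sds
        blocks.append((Y, Vobs, np.full(n, g)))

    Y = np.vstack([b[0] for b in blocks])
    Vobs = np.vstack([b[1] for b in blocks])
    grp = np.concatenate([b[2] for b in blocks]).astype(int)

    X = np.zeros(Y.shape, dtype=int)
    for i in range(p):
        X[:, i] = np.searchsorted(spec.thresholds[i], Y[:, i], side="left")

    item_names = [f"item{i + 1}" for i in range(p)]
    responses = pd.DataFrame(X, columns=item_names)
    group = pd.Series(grp, name="group") if G == 2 else None
    cov = (pd.DataFrame(Vobs, columns=[v.name for v in spec.violators])
           if nv else None)
    latent = pd.DataFrame(Y, columns=item_names) if return_latent else None
    return OrdinalDataset(responses=responses, group=group, covariates=cov, latent=latent)
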