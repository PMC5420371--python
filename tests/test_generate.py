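"""Synthetic ordinal data generator: determinism, invariants, round-trips."""

import numpy as np
import pytest
from scipy.stats import norm

from semdif.generate import (DifDef, GeneratorSpec, OrdinalDataset,
                             ViolatorDef, make_hads_like_spec, simulate)


def test_deterministic_for_fixed_seed():
    spec = make_hads_like_spec("uniform_dif")
    a = simulate(spec, n_per_group=300, seed=5)
    b = simulate(spec, n_per_group=300, seed=5)
    assert a.responses.equals(b.responses)
    assert a.group.equals(b.group)


def test_different_seeds_differ():
    spec = make_hads_like_spec("no_dif")
    a = simulate(spec, n_per_group=300, seed=5)
    b = simulate(spec, n_per_group=300, seed=6)
    assert not a.responses.equals(b.responses)


def test_zero_loading_margins():
    # all loadings 0, thresholds at quartiles -> ~25% per category
    q = norm.ppf([0.25, 0.5, 0.75])
    spec = GeneratorSpec(
        n_items=3, loadings=np.zeros(3), thresholds=np.tile(q, (3, 1)),
        factor_means=np.zeros((2, 1)), factor_sds=np.ones((2, 1)))
    d = simulate(spec, n_per_group=50000, seed=0)
    freq = d.responses.apply(lambda c: c.value_counts(normalize=True))
    assert np.allclose(freq.to_numpy(), 0.25, atol=0.01)


def test_uniform_group_dif_shifts_latent_mean_exactly():
    size = 0.5
    spec = make_hads_like_spec("uniform_dif", dif_size=size, dif_items=(2,))
    d = simulate(spec, n_per_group=40000, seed=3, return_latent=True)
    g = d.group.to_numpy()
    diff = (d.latent[g == 1].mean(axis=0) - d.latent[g == 0].mean(axis=0))
    assert diff["item3"] == pytest.approx(size, abs=0.02)
    others = diff.drop("item3").abs()
    assert (others < 0.02).all()


def test_interitem_correlations_near_lambda_product():
    spec = make_hads_like_spec("one_factor_7")
    d = simulate(spec, n_per_group=4000, seed=9, return_latent=True)
    R = np.corrcoef(d.latent.to_numpy().T)
    lam = spec.loadings
    want = np.outer(lam, lam)
    off = ~np.eye(7, dtype=bool)
    assert np.allclose(R[off], want[off], atol=0.05)


def test_spec_validation_errors():
    spec = make_hads_like_spec("no_dif")
    spec.thresholds = spec.thresholds[:, ::-1].copy()  # decreasing
    with pytest.raises(ValueError, match="increasing"):
        spec.validate()
    spec2 = make_hads_like_spec("no_dif")
    spec2.residual_sds = spec2.residual_sds * -1
    with pytest.raises(ValueError, match="positive"):
        spec2.validate()
    with pytest.raises(ValueError, match="unknown scenario"):
        make_hads_like_spec("bogus")


def test_yaml_round_trip(tmp_path):
    spec = make_hads_like_spec("two_factor_14")
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = GeneratorSpec.from_yaml(path)
    assert np.allclose(back.loadings, spec.loadings)
    assert np.allclose(back.thresholds, spec.thresholds)
    assert back.violators[0].name == "gender"
    assert back.n_factors == 2
    # round-tripped spec generates the identical dataset
    a = simulate(spec, n_per_group=100, seed=4)
    b = simulate(back, n_per_group=100, seed=4)
    assert a.responses.equals(b.responses)


def test_csv_round_trip(tmp_path):
    spec = make_hads_like_spec("two_factor_14")
    d = simulate(spec, n_per_group=200, seed=8)
    path = tmp_path / "d.csv"
    d.to_csv(path)
    back = OrdinalDataset.from_csv(path, covariates=["gender", "age"])
    assert back.responses.equals(d.responses)
    assert np.allclose(back.covariates.to_numpy(), d.covariates.to_numpy())


def test_group_homogeneity_without_dif():
    from scipy.stats import chi2_contingency
    spec = make_hads_like_spec("no_dif")
    bad = 0
    reps = 20
    for r in range(reps):
        d = simulate(spec, n_per_group=500, seed=100 + r)
        g = d.group.to_numpy()
        for i in range(7):
            tab = np.array([np.bincount(d.responses.iloc[:, i][g == k], minlength=4)
                            for k in (0, 1)])
            if chi2_contingency(tab)[1] < 0.01:
                bad += 1
    # nominal false-positive rate 1% over 140 tests
    assert bad <= 6
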