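"""Multidimensional (RFA) procedure: detection, gating, associations."""

import numpy as np
import pytest

from semdif.generate import DifDef, make_hads_like_spec, simulate
from semdif.multidim import effect_size_r, run_multidim


def test_effect_size_r():
    assert effect_size_r(0.25, 1.0, 1.0) == pytest.approx(0.25)
    assert effect_size_r(0.3, 2.0, 1.5) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        effect_size_r(0.2, 0.0, 1.0)


def test_direct_effect_detected_and_localized(md_data, md_stage1):
    rep = run_multidim(md_data, violators=("gender", "age"),
                       stage1_result=md_stage1)
    assert rep.procedure == "multidimensional"
    assert rep.findings, "injected direct effect was not detected"
    top = rep.findings[0]
    assert top.item == "item5"
    assert top.violator == "age"
    assert top.effect_size == pytest.approx(0.35, abs=0.12)
    assert top.important
    names = [t.name for t in rep.model_trail]
    assert names == ["Measurement Model", "No Item Bias Model", "Final Model"]
    assert rep.model_trail[0].fit.df == 76
    assert rep.model_trail[1].fit.df == 100
    assert rep.model_trail[2].fit.df == 100 - len(rep.findings)


def test_associations_recover_generator(md_data, md_stage1):
    rep = run_multidim(md_data, violators=("gender", "age"),
                       stage1_result=md_stage1)
    adj = {a.pair: a.r for a in rep.associations if a.context == "adjusted"}
    assert adj[("factor1", "factor2")] == pytest.approx(0.8, abs=0.07)
    assert adj[("age", "factor1")] == pytest.approx(-0.25, abs=0.08)
    assert adj[("gender", "factor1")] == pytest.approx(-0.15, abs=0.1)
    contexts = {a.context for a in rep.associations}
    assert contexts == {"adjusted", "unadjusted"}


def test_clean_data_search_gated():
    spec = make_hads_like_spec("two_factor_14")
    d = simulate(spec, n_per_group=1200, seed=55)
    rep = run_multidim(d, violators=("gender", "age"))
    assert rep.findings == []
    assert any("not started" in line or "no further" in line
               for line in rep.decisions_log)


def test_limitation_note_present(md_data, md_stage1):
    rep = run_multidim(md_data, violators=("gender", "age"),
                       stage1_result=md_stage1)
    assert any("Nonuniform" in n for n in rep.notes)


def test_unknown_violator_errors(md_data, md_stage1):
    with pytest.raises(ValueError, match="violators"):
        run_multidim(md_data, violators=("height",), stage1_result=md_stage1)
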