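"""Multigroup procedure: detection, gating, effect sizes, bookkeeping."""

import numpy as np
import pytest

from semdif.generate import make_hads_like_spec, simulate
from semdif.multigroup import (effect_size_nonuniform, effect_size_uniform,
                               run_multigroup)


def test_effect_size_formulas():
    assert effect_size_uniform(0.0, 0.4, 1.0) == pytest.approx(0.4)
    assert effect_size_nonuniform(0.6, 0.8, 0.0, 0.5, 1.0) == pytest.approx(0.1)
    # zero when latent means equal
    assert effect_size_nonuniform(0.6, 0.9, 0.2, 0.2, 1.0) == 0.0
    with pytest.raises(ValueError):
        effect_size_uniform(0.0, 0.4, 0.0)


def test_uniform_dif_detected_and_localized(mg_dif_data, mg_dif_stage1):
    rep = run_multigroup(mg_dif_data, stage1_result=mg_dif_stage1)
    assert rep.procedure == "multigroup"
    assert rep.findings, "injected DIF was not detected"
    top = rep.findings[0]
    assert top.item == "item3"
    assert top.type == "uniform"
    assert top.p < 1e-3
    assert top.effect_size == pytest.approx(0.5, abs=0.2)
    assert top.important
    # trail: Measurement -> No Item Bias -> Final
    names = [t.name for t in rep.model_trail]
    assert names == ["Measurement Model", "No Item Bias Model", "Final Model"]
    assert rep.model_trail[0].fit.df == 28
    assert rep.model_trail[1].fit.df == 40
    assert rep.model_trail[2].fit.df == 40 - len(rep.findings)
    # unadjusted latent difference absorbs part of the bias
    d_adj, _ = rep.true_difference_adjusted
    d_unadj, _ = rep.true_difference_unadjusted
    assert abs(d_adj) < abs(d_unadj)


def test_no_dif_search_gated(mg_clean_data, mg_clean_stage1):
    rep = run_multigroup(mg_clean_data, stage1_result=mg_clean_stage1)
    assert rep.findings == []
    assert any("search not started" in line or "no further" in line
               for line in rep.decisions_log)
    d_adj, p_adj = rep.true_difference_adjusted
    assert abs(d_adj) < 0.2


def test_nonuniform_dif_detected():
    spec = make_hads_like_spec("nonuniform_dif", dif_size=0.6, dif_items=(2,))
    d = simulate(spec, n_per_group=1500, seed=33)
    rep = run_multigroup(d)
    assert rep.findings
    assert rep.findings[0].item == "item3"
    assert rep.findings[0].type == "nonuniform"


def test_report_serialization(mg_dif_data, mg_dif_stage1, tmp_path):
    rep = run_multigroup(mg_dif_data, stage1_result=mg_dif_stage1)
    js = rep.to_json(tmp_path / "r.json")
    assert (tmp_path / "r.json").exists()
    assert '"multigroup"' in js
    tsv = rep.findings_tsv()
    from semdif.report import findings_from_tsv
    back = findings_from_tsv(tsv)
    assert [f.item for f in back] == [f.item for f in rep.findings]
    assert back[0].effect_size == pytest.approx(rep.findings[0].effect_size)
    trail = rep.trail_frame()
    assert list(trail["df"]) == [t.fit.df for t in rep.model_trail]
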