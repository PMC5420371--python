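"""Result containers and rendering for the item-bias detection procedures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO

import pandas as pd

from .sem import FitResult


@dataclass
class DifFinding:
    """One detected item bias."""

    item: str
    violator: str
    type: str  # "uniform" | "nonuniform"
    chisq_diff: float
    df_diff: int
    p: float
    effect_size: float
    important: bool
    step_index: int

    def as_dict(self) -> dict:
        return {
            "item": self.item, "violator": self.violator, "type": self.type,
            "chisq_diff": self.chisq_diff, "df_diff": self.df_diff, "p": self.p,
            "effect_size": self.effect_size, "important": self.important,
            "step_index": self.step_index,
        }


@dataclass
class TrailEntry:
    """One model in the Measurement -> No-Item-Bias -> ... -> Final sequence."""

    name: str
    fit: FitResult
    compared_to: str | None = None
    chisq_diff: float | None = None
    df_diff: int | None = None
    p_diff: float | None = None


@dataclass
class AssociationEstimate:
    """A factor/violator correlation, before or after bias adjustment."""

    pair: tuple[str, str]
    r: float
    p: float
    context: str  # "unadjusted" | "adjusted"

    def as_dict(self) -> dict:
        return {"pair": list(self.pair), "r": self.r, "p": self.p,
                "context": self.context}


@dataclass
class DifReport:
    """Full output of a bias-detection run."""

    procedure: str  # "multigroup" | "multidimensional"
    findings: list[DifFinding]
    model_trail: list[TrailEntry]
    true_difference_adjusted: tuple[float, float] | None = None  # (d, p)
    true_difference_unadjusted: tuple[float, float] | None = None
    associations: list[AssociationEstimate] = field(default_factory=list)
    flagged_pairs: list[tuple] = field(default_factory=list)
    decisions_log: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    # -- serialization ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "findings": [f.as_dict() for f in self.findings],
            "model_trail": [
                {"name": t.name, **t.fit.to_json_dict(),
                 "compared_to": t.compared_to, "chisq_diff": t.chisq_diff,
                 "df_diff": t.df_diff, "p_diff": t.p_diff}
                for t in self.model_trail
            ],
            "true_difference_adjusted": self.true_difference_adjusted,
            "true_difference_unadjusted": self.true_difference_unadjusted,
            "associations": [a.as_dict() for a in self.associations],
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "decisions_log": self.decisions_log,
            "notes": self.notes,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_json_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def findings_frame(self) -> pd.DataFrame:
        cols = ["item", "violator", "type", "chisq_diff", "df_diff", "p",
                "effect_size", "important", "step_index"]
        return pd.DataFrame([f.as_dict() for f in self.findings], columns=cols)

    def findings_tsv(self, path=None) -> str:
        buf = StringIO()
        self.findings_frame().to_csv(buf, sep="\t", index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(buf.getvalue())
        return buf.getvalue()

    def trail_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.model_trail:
            rows.append({
                "model": t.name, "df": t.fit.df, "chisq": t.fit.chisq_wls,
                "p_value": t.fit.p_value, "rmsea": t.fit.rmsea,
                "rmsea_lo90": t.fit.rmsea_ci[0], "rmsea_hi90": t.fit.rmsea_ci[1],
                "compared_to": t.compared_to, "chisq_diff": t.chisq_diff,
                "df_diff": t.df_diff, "p_diff": t.p_diff,
            })
        return pd.DataFrame(rows)

    def trail_tsv(self, path=None) -> str:
        buf = StringIO()
        self.trail_frame().to_csv(buf, sep="\t", index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(buf.getvalue())
        return buf.getvalue()


def findings_from_tsv(text: str) -> list[DifFinding]:
    """Inverse of :meth:`DifReport.findings_tsv` (round-trip support)."""
    df = pd.read_csv(StringIO(text), sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(DifFinding(
            item=str(r["item"]), violator=str(r["violator"]), type=str(r["type"]),
            chisq_diff=float(r["chisq_diff"]), df_diff=int(r["df_diff"]),
            p=float(r["p"]), effect_size=float(r["effect_size"]),
            important=bool(r["important"]), step_index=int(r["step_index"]),
        ))
    return out
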