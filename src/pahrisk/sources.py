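"""Rule-based PAH source diagnostics.

Six conventional congener diagnostic ratios are computed per sample and
classified against literature threshold bands (pyrogenic vs petrogenic,
fuel vs biomass combustion, gasoline vs diesel traffic, ...).  Intervals are
half-open ``[low, high)``: a ratio exactly on a breakpoint takes the label
of the band it opens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .profiles import CongenerProfile, lmw_hmw_split

#: Flag label propagated when a ratio's denominator is zero.
UNDEFINED = "undefined"


@dataclass(frozen=True)
class DiagnosticRule:
    """One diagnostic ratio with its classification bands.

    ``breakpoints`` are strictly increasing; ``labels`` has one more entry
    than ``breakpoints``.  Values in ``[breakpoints[i-1], breakpoints[i])``
    take ``labels[i]``.
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError(f"{self.name}: breakpoints must strictly increase")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError(f"{self.name}: need one more label than breakpoints")

    def classify(self, value: float) -> str:
        """Label for a ratio value; ``UNDEFINED`` propagates unchanged."""
        if math.isnan(value):
            return UNDEFINED
        if value < 0:
            raise ValueError(f"{self.name}: ratio must be >= 0, got {value}")
        i = 0
        while i < len(self.breakpoints) and value >= self.breakpoints[i]:
            i += 1
        return self.labels[i]


RULES: dict[str, DiagnosticRule] = {
    r.name: r
    for r in (
        DiagnosticRule("LMW/HMW", (1.0,), ("pyrogenic", "petrogenic")),
        DiagnosticRule("ANT/(ANT+PHE)", (0.1,), ("petrogenic", "pyrogenic")),
        DiagnosticRule(
            "IcP/(IcP+BgP)", (0.2, 0.5),
            ("petrogenic", "fuel combustion", "grass/wood/coal combustion"),
        ),
        DiagnosticRule(
            "BaA/CYR", (0.2, 0.35),
            ("unclassified", "coal combustion", "vehicular emissions"),
        ),
        DiagnosticRule(
            "BaA/(BaA+CYR)", (0.2, 0.35),
            ("petrogenic", "mixed", "combustion"),
        ),
        DiagnosticRule("FLU/(FLU+PYR)", (0.5,), ("gasoline", "diesel")),
    )
}


@dataclass(frozen=True)
class SourceCall:
    sample_id: str
    rule: str
    value: float  # nan when undefined
    label: str


def _ratio(num: float, den: float) -> float:
    return float("nan") if den == 0 else num / den


def compute_diagnostic_ratios(p: CongenerProfile) -> dict[str, float]:
    """The six named diagnostic ratios for one imputed profile.

    A zero denominator yields NaN, which classifies to ``undefined`` and is
    excluded from that rule's tallies downstream.
    """
    p._require_imputed("compute_diagnostic_ratios")
    c = p.conc
    lmw, hmw = lmw_hmw_split(p)
    return {
        "LMW/HMW": _ratio(lmw, hmw),
        "ANT/(ANT+PHE)": _ratio(c["ANT"], c["ANT"] + c["PHE"]),
        "IcP/(IcP+BgP)": _ratio(c["IcP"], c["IcP"] + c["BgP"]),
        "BaA/CYR": _ratio(c["BaA"], c["CYR"]),
        "BaA/(BaA+CYR)": _ratio(c["BaA"], c["BaA"] + c["CYR"]),
        "FLU/(FLU+PYR)": _ratio(c["FLU"], c["FLU"] + c["PYR"]),
    }


def classify_source(rule: DiagnosticRule | str, value: float) -> str:
    """Deterministic source label for one ratio value under one rule."""
    if isinstance(rule, str):
        rule = RULES[rule]
    return rule.classify(value)


def source_calls(p: CongenerProfile) -> list[SourceCall]:
    """All six classified ratio calls for one sample."""
    return [
        SourceCall(p.sample_id, name, value, classify_source(name, value))
        for name, value in compute_diagnostic_ratios(p).items()
    ]


def source_calls_frame(profiles: list[CongenerProfile]) -> pd.DataFrame:
    """Long-format table ``sample_id, rule, value, label`` for many samples."""
    rows = [
        {"sample_id": c.sample_id, "rule": c.rule,
         "value": c.value, "label": c.label}
        for p in profiles
        for c in source_calls(p)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "rule", "value", "label"])


def tally_labels(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-rule label counts and percentages, excluding undefined ratios."""
    ok = calls[calls["label"] != UNDEFINED]
    counts = ok.groupby(["rule", "label"]).size().rename("n").reset_index()
    counts["percent"] = counts.groupby("rule")["n"].transform(
        lambda s: 100.0 * s / s.sum()
    )
    return counts
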