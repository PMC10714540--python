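"""Contingency tables, diagnostic metrics and evidence-strength mapping.

Evidence performance is summarised by sensitivity, specificity, positive
predictive value and the positive likelihood ratio
``LR+ = sensitivity / (1 - specificity)``.  LR+ maps onto ACMG/AMP evidence
strengths via the Tavtigian-framework thresholds: supporting (LR+ >= 2.08),
moderate (>= 4.33) and strong (>= 18.71); all boundaries inclusive.  A
likelihood ratio with zero false positives is reported as a flagged infinity
(category strong), never numerically capped.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import pandas as pd

#: Inclusive lower LR+ bounds for each evidence-strength category.
STRENGTH_THRESHOLDS: dict[str, float] = {
    "supporting": 2.08,
    "moderate": 4.33,
    "strong": 18.71,
}

REPORT_COLUMNS = [
    "criterion", "rule", "direction", "filter",
    "tp", "fp", "fn", "tn", "unique", "conflicting",
    "sens", "spec", "ppv", "lr_plus", "strength",
]


@dataclass
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int
    n_unique: int = 0
    n_conflicting: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "n_unique", "n_conflicting"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn,
            self.tn + other.tn, self.n_unique + other.n_unique,
            self.n_conflicting + other.n_conflicting,
        )


@dataclass
class Metrics:
    sensitivity: float
    specificity: float
    ppv: float
    lr_plus: float  # math.inf when no false positives
    lr_infinite: bool
    strength: str

    def rounded(self, ndigits: int = 3) -> dict:
        d = asdict(self)
        for k in ("sensitivity", "specificity", "ppv", "lr_plus"):
            if isinstance(d[k], float) and math.isfinite(d[k]):
                d[k] = round(d[k], ndigits)
        return d


def lr_to_strength(lr_plus: float) -> str:
    """Highest evidence-strength category whose LR+ threshold is met."""
    if lr_plus < 0:
        raise ValueError(f"LR+ must be non-negative, got {lr_plus}")
    strength = "below"
    for name, bound in STRENGTH_THRESHOLDS.items():
        if lr_plus >= bound:
            strength = name
    return strength


def compute_metrics(table: ContingencyTable) -> Metrics:
    """Sensitivity, specificity, PPV and LR+ from a contingency table.

    Requires at least one variant in each truth class; an empty class makes
    every rate degenerate and is rejected.
    """
    if table.tp + table.fn == 0:
        raise ValueError("no positive-class variants; metrics undefined")
    if table.tn + table.fp == 0:
        raise ValueError("no negative-class variants; metrics undefined")
    sens = table.tp / (table.tp + table.fn)
    spec = table.tn / (table.tn + table.fp)
    ppv = table.tp / (table.tp + table.fp) if table.tp + table.fp else math.nan
    if table.fp == 0:
        lr, infinite = math.inf, True
    else:
        lr, infinite = sens / (1 - spec), False
    return Metrics(sens, spec, ppv, lr, infinite, lr_to_strength(lr))


def report_row(
    criterion: str,
    rule: str | None,
    direction: str,
    variant_filter: str,
    table: ContingencyTable,
) -> dict:
    """One results row; degenerate strata are marked not-evaluable, not dropped."""
    row = {
        "criterion": criterion,
        "rule": rule or "",
        "direction": direction,
        "filter": variant_filter,
        "tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn,
        "unique": table.n_unique, "conflicting": table.n_conflicting,
    }
    try:
        m = compute_metrics(table)
        row.update(
            sens=m.sensitivity, spec=m.specificity, ppv=m.ppv,
            lr_plus=m.lr_plus, strength=m.strength,
        )
    except ValueError:
        row.update(sens=math.nan, spec=math.nan, ppv=math.nan,
                   lr_plus=math.nan, strength="not_evaluable")
    return row


def build_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-analysis rows into the results table layout."""
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        report.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        records = report.replace({math.inf: "inf"}).to_dict(orient="records")
        with open(json_path, "w") as fh:
            json.dump(records, fh, indent=2, default=str)
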