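"""Variant co-localisation evidence: standard and meta-position PM5.

The ACMG/AMP PM5 criterion treats a *different* pathogenic missense change at
the same residue of the same protein as evidence of pathogenicity.  Here that
logic is extended in two directions:

* a benign mirror (a different benign missense change at the residue supports
  benignity), and
* meta-position PM5 — pooling clinically annotated variants at structurally
  equivalent positions across all paralogous instances of a domain family.

Meta-positions carrying two or more variants are assigned a label under one of
two conflict policies: the *no-conflict* rule (any disagreement voids the
assignment) or the *majority* rule (plurality wins; exact ties conflict).
Positions with a single variant are ``unique`` and yield no evidence.

A cascade applies standard PM5 first (strong evidence when positive) and falls
back to meta-position evidence (moderate) for in-domain variants the standard
analysis misses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from metadomain.evaluation import ContingencyTable

Rule = Literal["no_conflict", "majority"]
Direction = Literal["pathogenic", "benign"]

POSITION_KEY = ["protein_id", "residue_index"]
CHANGE_KEY = POSITION_KEY + ["ref_aa", "alt_aa"]
META_KEY = ["family_id", "column_label"]

_OPPOSITE = {"pathogenic": "benign", "benign": "pathogenic"}


@dataclass
class MetaPositionSummary:
    """Label counts at a (meta-)position and its assignment under a rule."""

    n_pathogenic: int
    n_benign: int
    assignment: str  # pathogenic | benign | conflicting | unique | empty
    rule: Rule


@dataclass
class EvidenceOutcome:
    criterion: str  # PM5_same_protein | PM5_meta | PM5_benign_same_protein | PM5_benign_meta | none
    direction: str  # pathogenic | benign | none
    strength: str  # strong | moderate | none
    role: str | None = None  # TP | FP | FN | TN for a labelled query
    in_domain: bool | None = None


def summarize_position(labels: Iterable[str], rule: Rule = "no_conflict") -> MetaPositionSummary:
    """Assign a position from the multiset of its clinical labels.

    Two or more concordant variants assign the position to their shared label;
    a single variant is ``unique``; no variants is ``empty``.  Mixed labels
    are ``conflicting`` under the no-conflict rule, while the majority rule
    sides with the more common label and conflicts only on an exact tie.
    """
    if rule not in ("no_conflict", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    counts = Counter(labels)
    unknown = set(counts) - {"pathogenic", "benign"}
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    p, b = counts["pathogenic"], counts["benign"]
    total = p + b
    if total == 0:
        assignment = "empty"
    elif total == 1:
        assignment = "unique"
    elif b == 0:
        assignment = "pathogenic"
    elif p == 0:
        assignment = "benign"
    elif rule == "no_conflict" or p == b:
        assignment = "conflicting"
    else:
        assignment = "pathogenic" if p > b else "benign"
    return MetaPositionSummary(p, b, assignment, rule)


def _assign_vectorised(p: np.ndarray, b: np.ndarray, rule: Rule) -> np.ndarray:
    total = p + b
    if rule == "no_conflict":
        conflict = (p > 0) & (b > 0)
        path = (b == 0) & (p >= 2)
        ben = (p == 0) & (b >= 2)
    else:
        conflict = (p > 0) & (b > 0) & (p == b)
        path = (p >= 2) & (p > b)
        ben = (b >= 2) & (b > p)
    return np.select(
        [total == 0, total == 1, path, ben, conflict],
        ["empty", "unique", "pathogenic", "benign", "conflicting"],
        default="conflicting",
    )


# ---------------------------------------------------------------------------
# vectorised per-variant evaluation


def evaluate_standard(dataset: pd.DataFrame, direction: Direction = "pathogenic") -> pd.DataFrame:
    """Same-protein co-localisation outcome for every variant in ``dataset``.

    For each query, co-localised evidence consists of variants at the same
    (protein, residue) whose amino-acid change differs from the query's; the
    outcome is positive iff at least one such variant exists and all of them
    carry the ``direction`` label.  Returns a frame aligned to
    ``dataset.index`` with ``positive``, ``unique`` and ``conflict`` flags.
    """
    df = dataset
    pos_counts = (
        df.groupby(POSITION_KEY)["label"]
        .agg(pos_path=lambda s: (s == "pathogenic").sum(),
             pos_ben=lambda s: (s == "benign").sum())
        .reset_index()
    )
    chg_counts = (
        df.groupby(CHANGE_KEY)["label"]
        .agg(chg_path=lambda s: (s == "pathogenic").sum(),
             chg_ben=lambda s: (s == "benign").sum())
        .reset_index()
    )
    m = df[CHANGE_KEY + ["label"]].merge(pos_counts, on=POSITION_KEY, how="left")
    m = m.merge(chg_counts, on=CHANGE_KEY, how="left")
    others_path = (m["pos_path"] - m["chg_path"]).to_numpy()
    others_ben = (m["pos_ben"] - m["chg_ben"]).to_numpy()
    if direction == "pathogenic":
        same, other = others_path, others_ben
    else:
        same, other = others_ben, others_path
    out = pd.DataFrame(index=dataset.index)
    out["positive"] = (same >= 1) & (other == 0)
    out["unique"] = (others_path + others_ben) == 0
    out["conflict"] = (others_path >= 1) & (others_ben >= 1)
    return out


def evaluate_meta(
    dataset: pd.DataFrame,
    mapping: pd.DataFrame,
    rule: Rule = "no_conflict",
    direction: Direction = "pathogenic",
    leave_one_out: bool = False,
    include_insertions: bool = True,
) -> pd.DataFrame:
    """Meta-position outcome for every variant, via the residue mapping.

    The meta-position assignment pools *all* clinical variants mapped to the
    (family, column) label — the query's own record included, unless
    ``leave_one_out`` recomputes each assignment with the query removed.  A
    residue inside two overlapping domain annotations is scored against each
    family and the most evidential outcome is reported.
    """
    if not include_insertions:
        mapping = mapping[~mapping["is_insertion"]]
    joined = (
        dataset[POSITION_KEY + ["label"]]
        .reset_index(names="_query")
        .merge(mapping[POSITION_KEY + META_KEY], on=POSITION_KEY, how="left")
    )
    out = pd.DataFrame(index=dataset.index)
    mapped = joined[joined["family_id"].notna()].copy()
    out["in_domain"] = False
    out.loc[joined.loc[joined["family_id"].notna(), "_query"].unique(), "in_domain"] = True
    if mapped.empty:
        out["positive"] = False
        out["unique"] = False
        out["conflict"] = False
        return out
    counts = (
        mapped.groupby(META_KEY)["label"]
        .agg(mp_path=lambda s: (s == "pathogenic").sum(),
             mp_ben=lambda s: (s == "benign").sum())
        .reset_index()
    )
    mapped = mapped.merge(counts, on=META_KEY, how="left")
    p = mapped["mp_path"].to_numpy(dtype=int)
    b = mapped["mp_ben"].to_numpy(dtype=int)
    if leave_one_out:
        p = p - (mapped["label"] == "pathogenic").to_numpy(dtype=int)
        b = b - (mapped["label"] == "benign").to_numpy(dtype=int)
    assignment = _assign_vectorised(p, b, rule)
    mapped["_positive"] = assignment == direction
    mapped["_unique"] = assignment == "unique"
    mapped["_conflict"] = assignment == "conflicting"
    agg = mapped.groupby("_query").agg(
        positive=("_positive", "any"),
        unique=("_unique", "all"),
        conflict=("_conflict", "any"),
    )
    for col in ("positive", "unique", "conflict"):
        out[col] = False
        out.loc[agg.index, col] = agg[col]
    out["conflict"] = out["conflict"] & ~out["positive"]
    out["unique"] = out["unique"] & out["in_domain"]
    return out


def contingency(
    dataset: pd.DataFrame, outcome: pd.DataFrame, direction: Direction
) -> ContingencyTable:
    """Tabulate per-variant outcomes into TP/FP/FN/TN for one direction.

    Positives at the query's own label being ``direction`` are true positives;
    every non-positive query (opposite assignment, conflict or unique) counts
    against sensitivity, mirroring the contingency definitions used for both
    the pathogenic and the benign analyses.
    """
    is_dir = (dataset["label"] == direction).to_numpy()
    pos = outcome["positive"].to_numpy()
    return ContingencyTable(
        tp=int((pos & is_dir).sum()),
        fp=int((pos & ~is_dir).sum()),
        fn=int((~pos & is_dir).sum()),
        tn=int((~pos & ~is_dir).sum()),
        n_unique=int(outcome["unique"].sum()),
        n_conflicting=int(outcome["conflict"].sum()),
    )


def evaluate_cascade(
    dataset: pd.DataFrame,
    mapping: pd.DataFrame,
    rule: Rule = "no_conflict",
    direction: Direction = "pathogenic",
) -> pd.DataFrame:
    """Sequential evidence: standard PM5 (strong), else meta-position (moderate).

    Returns per-variant ``criterion``/``strength`` plus a combined
    ``positive`` flag; the meta stage is only consulted for variants without
    same-protein evidence and only inside mapped domains.
    """
    std = evaluate_standard(dataset, direction)
    meta = evaluate_meta(dataset, mapping, rule, direction)
    prefix = "PM5" if direction == "pathogenic" else "PM5_benign"
    out = pd.DataFrame(index=dataset.index)
    std_pos = std["positive"].to_numpy()
    meta_pos = (~std_pos) & meta["positive"].to_numpy() & meta["in_domain"].to_numpy()
    out["criterion"] = np.select(
        [std_pos, meta_pos], [f"{prefix}_same_protein", f"{prefix}_meta"], default="none"
    )
    out["strength"] = np.select([std_pos, meta_pos], ["strong", "moderate"], default="none")
    out["positive"] = std_pos | meta_pos
    out["unique"] = std["unique"] & (meta["unique"] | ~meta["in_domain"])
    out["conflict"] = (std["conflict"] | meta["conflict"]) & ~out["positive"]
    out["in_domain"] = meta["in_domain"]
    return out


# ---------------------------------------------------------------------------
# single-query API


def _locate(query, dataset: pd.DataFrame) -> int:
    key = ["chrom", "pos", "ref", "alt"]
    mask = pd.Series(True, index=dataset.index)
    for k in key:
        mask &= dataset[k] == query[k]
    idx = dataset.index[mask]
    if len(idx) == 0:
        raise ValueError(f"query variant {tuple(query[k] for k in key)} absent from dataset")
    return idx[0]


def _role(label: str, positive: bool, direction: str) -> str:
    if positive:
        return "TP" if label == direction else "FP"
    return "FN" if label == direction else "TN"


def classify_standard_pm5(query, dataset: pd.DataFrame,
                          direction: Direction = "pathogenic") -> EvidenceOutcome:
    """Evidence from a different missense variant at the query's own residue."""
    idx = _locate(query, dataset)
    res = evaluate_standard(dataset, direction).loc[idx]
    prefix = "PM5" if direction == "pathogenic" else "PM5_benign"
    positive = bool(res["positive"])
    return EvidenceOutcome(
        criterion=f"{prefix}_same_protein" if positive else "none",
        direction=direction if positive else "none",
        strength="strong" if positive else "none",
        role=_role(dataset.loc[idx, "label"], positive, direction),
    )


def classify_benign_pm5(query, dataset: pd.DataFrame) -> EvidenceOutcome:
    return classify_standard_pm5(query, dataset, direction="benign")


def classify_meta_pm5(query, dataset: pd.DataFrame, mapping: pd.DataFrame,
                      rule: Rule = "no_conflict",
                      direction: Direction = "pathogenic") -> EvidenceOutcome:
    """Evidence from the assignment of the query's meta-position(s)."""
    idx = _locate(query, dataset)
    res = evaluate_meta(dataset, mapping, rule, direction).loc[idx]
    prefix = "PM5" if direction == "pathogenic" else "PM5_benign"
    in_domain = bool(res["in_domain"])
    positive = bool(res["positive"]) and in_domain
    return EvidenceOutcome(
        criterion=f"{prefix}_meta" if positive else "none",
        direction=direction if positive else "none",
        strength="moderate" if positive else "none",
        role=_role(dataset.loc[idx, "label"], positive, direction) if in_domain else None,
        in_domain=in_domain,
    )


def cascade_pm5(query, dataset: pd.DataFrame, mapping: pd.DataFrame,
                rule: Rule = "no_conflict",
                direction: Direction = "pathogenic") -> EvidenceOutcome:
    """Standard PM5 first; meta-position evidence as an in-domain fallback."""
    std = classify_standard_pm5(query, dataset, direction)
    if std.strength == "strong":
        return std
    meta = classify_meta_pm5(query, dataset, mapping, rule, direction)
    if meta.strength == "moderate":
        return meta
    idx = _locate(query, dataset)
    return EvidenceOutcome(
        criterion="none", direction="none", strength="none",
        role=_role(dataset.loc[idx, "label"], False, direction),
        in_domain=meta.in_domain,
    )
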