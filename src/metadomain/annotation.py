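"""Joining clinical assertions, population observations and predictor scores
onto the simulated SNV universe.

Clinical assertions are pooled to a binary label: pathogenic (P/LP) or benign
(B/LB); variants with any conflicting or other classification are dropped.
Population observations are used as presence/absence of a PASS-filtered site.
REVEL-style scores are keyed by chromosome, position and the amino-acid
change, and support an optional pre-filter (pathogenic kept at score >= 0.7,
benign at <= 0.2) for sensitivity analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]
PATHOGENIC_CLASSES = {"P", "LP"}
BENIGN_CLASSES = {"B", "LB"}


def _check_unique(df: pd.DataFrame, key: list[str], source: str) -> None:
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate key in {source}: {first}")


def filter_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Pool per-submission classifications into one unconflicting label per variant.

    A variant is kept iff all of its classifications lie within {P, LP}
    (label ``pathogenic``) or all within {B, LB} (label ``benign``); variants
    with VUS/other/conflicting classifications are dropped.  Records with a
    malformed variant key are skipped with a log entry.
    """
    records = records.copy()
    bad = records["pos"].isna() | records["ref"].isna() | records["alt"].isna()
    for col in ("ref", "alt"):
        bad |= ~records[col].astype(str).str.fullmatch("[ACGT]")
    if bad.any():
        logger.warning("skipping %d clinical records with malformed variant keys", int(bad.sum()))
        records = records[~bad]
    records["pos"] = records["pos"].astype(int)

    def pool(classes: pd.Series) -> str | None:
        s = set(classes)
        if s <= PATHOGENIC_CLASSES:
            return "pathogenic"
        if s <= BENIGN_CLASSES:
            return "benign"
        return None

    grouped = (
        records.groupby(VARIANT_KEY, sort=False)["classification"]
        .agg(pool)
        .rename("label")
        .reset_index()
    )
    return grouped[grouped["label"].notna()].reset_index(drop=True)


def annotate_universe(
    variants: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    population: pd.DataFrame | None = None,
    revel: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Left-join annotation sources onto the simulated SNV universe.

    Returns the annotated table (same rows as ``variants``) and a report of
    unmatched annotation records per source.  Population rows whose FILTER is
    not PASS are excluded before the join; ``observed`` marks the presence of
    a distinct PASS site.  Duplicate keys within a source are rejected.
    """
    out = variants.copy()
    report: dict[str, int] = {}

    if clinical is not None:
        if "label" not in clinical.columns:
            clinical = filter_clinical(clinical)
        _check_unique(clinical, VARIANT_KEY, "clinical")
        merged = out.merge(clinical[VARIANT_KEY + ["label"]], on=VARIANT_KEY, how="left")
        matched = merged["label"].notna().sum()
        report["clinical_unmatched"] = int(len(clinical) - clinical.merge(
            out[VARIANT_KEY].drop_duplicates(), on=VARIANT_KEY, how="inner").shape[0])
        out = merged
        logger.info("clinical: %d labels joined, %d unmatched", matched,
                    report["clinical_unmatched"])
    else:
        out["label"] = np.nan

    if population is not None:
        passed = population[population["filter"].astype(str) == "PASS"]
        passed = passed.drop_duplicates(subset=VARIANT_KEY)
        _check_unique(passed, VARIANT_KEY, "population")
        keep = [c for c in ("AC", "AN") if c in passed.columns]
        merged = out.merge(
            passed[VARIANT_KEY + keep].assign(observed=True),
            on=VARIANT_KEY, how="left",
        )
        merged["observed"] = merged["observed"].eq(True)
        report["population_unmatched"] = int(len(passed) - passed.merge(
            out[VARIANT_KEY].drop_duplicates(), on=VARIANT_KEY, how="inner").shape[0])
        out = merged
    else:
        out["observed"] = False

    if revel is not None:
        key = ["chrom", "pos", "ref_aa", "alt_aa"]
        rv = revel.drop_duplicates(subset=key)
        _check_unique(rv, key, "revel")
        out = out.merge(rv[key + ["revel"]], on=key, how="left")
        report["revel_unmatched"] = int(len(rv) - rv.merge(
            out[key].drop_duplicates(), on=key, how="inner").shape[0])
    else:
        out["revel"] = np.nan

    return out, report


def revel_filter(
    assertions: pd.DataFrame,
    path_min: float = 0.7,
    ben_max: float = 0.2,
) -> pd.DataFrame:
    """Keep pathogenic variants scoring >= ``path_min`` and benign <= ``ben_max``.

    Both comparisons are inclusive.  Variants without a score are dropped in
    this mode (never imputed).
    """
    for name, value in (("path_min", path_min), ("ben_max", ben_max)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be within [0, 1], got {value}")
    scored = assertions[assertions["revel"].notna()]
    keep = (
        ((scored["label"] == "pathogenic") & (scored["revel"] >= path_min))
        | ((scored["label"] == "benign") & (scored["revel"] <= ben_max))
    )
    return scored[keep].reset_index(drop=True)
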