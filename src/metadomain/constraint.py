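"""Meta-domain missense constraint and its evaluation as PP2-style evidence.

The constraint score is a background-adjusted missense/synonymous ratio
(a dN/dS-style statistic) computed over all paralogous instances of a domain
family:

    adjusted m/s = sum(missense_obs / missense_poss)
                   / sum(synonymous_obs / synonymous_poss)

where *poss* is the number of possible SNVs of each consequence class given
the codon composition (nine per codon in total), and *obs* is the number of
distinct PASS-filtered population variants actually observed.  The sums run
over all non-insertion alignment positions of all family members; each
genomic coordinate contributes at most once per family (but may contribute
to several families).  Low adjusted m/s means the family's meta-domain is
depleted of missense variation, i.e. under purifying selection.

Externally computed per-gene and per-region constraint metrics (missense Z,
missense o/e, CCR percentiles) are consumed as score tables and evaluated by
the same thresholding machinery; a mirrored benign threshold is placed at the
same number of standard deviations from the score mean on the opposite side
(for CCR percentile ranks, simply 100 minus the pathogenic threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd

from metadomain.evaluation import ContingencyTable
from metadomain.transcripts import BASES, GENETIC_CODE

Direction = Literal["pathogenic", "benign"]

CONSTRAINT_COLUMNS = [
    "family_id", "adjusted_ms", "raw_ms", "n_positions", "n_members",
]


@dataclass(frozen=True)
class PossibleCounts:
    missense: int
    synonymous: int
    nonsense: int


@lru_cache(maxsize=None)
def count_possible(codon: str) -> PossibleCounts:
    """Consequence partition of the nine possible SNVs of a sense codon."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    ref_aa = GENETIC_CODE[codon]
    if ref_aa == "*":
        raise ValueError(f"{codon} is a stop codon; constraint counts cover sense codons")
    mis = syn = non = 0
    for j in range(3):
        for alt in BASES:
            if alt == codon[j]:
                continue
            alt_aa = GENETIC_CODE[codon[:j] + alt + codon[j + 1:]]
            if alt_aa == "*":
                non += 1
            elif alt_aa == ref_aa:
                syn += 1
            else:
                mis += 1
    return PossibleCounts(mis, syn, non)


def position_counts(universe: pd.DataFrame) -> pd.DataFrame:
    """Per-residue possible/observed consequence counts from the SNV universe.

    ``universe`` is the exhaustive simulated-variant table carrying an
    ``observed`` flag for distinct PASS population sites.  Returns one row per
    (protein_id, residue_index) with poss/obs counts and the codon's genomic
    coordinate key used for cross-transcript deduplication.
    """
    df = universe[universe["consequence"].isin(["missense", "synonymous"])].copy()
    obs = df["observed"].to_numpy(dtype=bool)
    is_mis = (df["consequence"] == "missense").to_numpy()
    df["_mis_poss"] = is_mis.astype(int)
    df["_syn_poss"] = (~is_mis).astype(int)
    df["_mis_obs"] = (is_mis & obs).astype(int)
    df["_syn_obs"] = (~is_mis & obs).astype(int)
    rows = (
        df.groupby(["protein_id", "residue_index"], sort=False)
        .agg(chrom=("chrom", "first"),
             pos_min=("pos", "min"), pos_max=("pos", "max"), pos_sum=("pos", "sum"),
             missense_poss=("_mis_poss", "sum"),
             synonymous_poss=("_syn_poss", "sum"),
             missense_obs=("_mis_obs", "sum"),
             synonymous_obs=("_syn_obs", "sum"))
        .reset_index()
    )
    # min/max/sum of the codon's three genomic coordinates identify the codon
    rows["coord_key"] = (rows["chrom"].astype(str) + ":" + rows["pos_min"].astype(str)
                         + "-" + rows["pos_max"].astype(str) + ":" + rows["pos_sum"].astype(str))
    return rows.drop(columns=["pos_min", "pos_max", "pos_sum"])


def adjusted_ms_scores(
    universe: pd.DataFrame,
    mapping: pd.DataFrame,
    per_position: bool = True,
) -> pd.DataFrame:
    """Constraint score per domain family.

    Insertion-labelled positions are excluded; positions are deduplicated
    within a family by genomic coordinates so that a locus shared by several
    transcripts counts once.  ``per_position=True`` (default) sums
    per-position obs/poss ratios; the pooled alternative divides class-wise
    pooled ratios instead and is provided for sensitivity analysis.  Families
    whose synonymous denominator is zero get a missing score, never 0.
    """
    per_res = position_counts(universe)
    mp = mapping[~mapping["is_insertion"]][["protein_id", "residue_index", "family_id"]]
    joined = mp.merge(per_res, on=["protein_id", "residue_index"], how="inner")
    joined = joined.drop_duplicates(subset=["family_id", "coord_key"])
    out = []
    for fam, g in joined.groupby("family_id", sort=True):
        if per_position:
            # complete-case positions only: a codon with no possible change of
            # one class (e.g. Met/Trp lack synonymous SNVs) cannot contrast the
            # two classes, and keeping it would re-introduce the composition
            # effect the adjustment removes (neutral expectation would drift
            # to N_mis/N_syn instead of 1)
            g = g[(g["missense_poss"] > 0) & (g["synonymous_poss"] > 0)]
            num = float((g["missense_obs"] / g["missense_poss"]).sum())
            den = float((g["synonymous_obs"] / g["synonymous_poss"]).sum())
        else:
            mobs, mposs = g["missense_obs"].sum(), g["missense_poss"].sum()
            sobs, sposs = g["synonymous_obs"].sum(), g["synonymous_poss"].sum()
            num = mobs / mposs if mposs else np.nan
            den = sobs / sposs if sposs else np.nan
        adj = num / den if den and den > 0 else np.nan
        sobs_total = g["synonymous_obs"].sum()
        raw = g["missense_obs"].sum() / sobs_total if sobs_total else np.nan
        n_members = mapping.loc[mapping["family_id"] == fam, "protein_id"].nunique()
        out.append((fam, adj, raw, len(g), n_members))
    return pd.DataFrame(out, columns=CONSTRAINT_COLUMNS)


@dataclass
class MetricSpec:
    """A constraint metric with thresholds and comparison directions.

    ``pathogenic_op`` is the comparison a score must satisfy against the
    pathogenic threshold for the variant to be called constrained: ``le`` for
    metrics where low means constrained (adjusted m/s, missense o/e), ``ge``
    for metrics where high does (missense Z, CCR percentile).
    """

    name: str
    scope: str = "meta-domain"
    pathogenic_threshold: float | None = None
    pathogenic_op: Literal["le", "ge"] = "le"
    benign_threshold: float | None = None
    benign_op: Literal["le", "ge"] = "ge"

    def __post_init__(self) -> None:
        for t in (self.pathogenic_threshold, self.benign_threshold):
            if t is not None and not np.isfinite(t):
                raise ValueError(f"{self.name}: thresholds must be finite")
        if (self.pathogenic_threshold is not None and self.benign_threshold is not None
                and self.pathogenic_op == self.benign_op):
            raise ValueError(f"{self.name}: pathogenic and benign comparisons must oppose")

    def meets(self, scores: np.ndarray, direction: Direction) -> np.ndarray:
        thr = (self.pathogenic_threshold if direction == "pathogenic"
               else self.benign_threshold)
        op = self.pathogenic_op if direction == "pathogenic" else self.benign_op
        if thr is None:
            raise ValueError(f"{self.name}: no {direction} threshold configured")
        with np.errstate(invalid="ignore"):
            met = scores <= thr if op == "le" else scores >= thr
        return np.where(np.isnan(scores), False, met)


def evaluate_metric(
    scored: pd.DataFrame,
    spec: MetricSpec,
    direction: Direction = "pathogenic",
) -> tuple[ContingencyTable, int]:
    """Contingency table for labelled variants against a metric threshold.

    ``scored`` needs ``label`` and ``score`` columns.  Variants without a
    score never meet a threshold; their number is returned alongside.
    """
    scores = scored["score"].to_numpy(dtype=float)
    met = spec.meets(scores, direction)
    is_dir = (scored["label"] == direction).to_numpy()
    table = ContingencyTable(
        tp=int((met & is_dir).sum()),
        fp=int((met & ~is_dir).sum()),
        fn=int((~met & is_dir).sum()),
        tn=int((~met & ~is_dir).sum()),
    )
    return table, int(np.isnan(scores).sum())


def threshold_sweep(
    scored: pd.DataFrame,
    n_steps: int = 1000,
    op: Literal["le", "ge"] = "le",
    direction: Direction = "pathogenic",
) -> pd.DataFrame:
    """LR+ over ``n_steps`` equally spaced thresholds from min to max score.

    Thresholds outside which a contingency cell empties give undefined LR+;
    such points are emitted with ``defined=False`` rather than dropped.
    """
    scores = scored["score"].to_numpy(dtype=float)
    labels = scored["label"].to_numpy()
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    if len(np.unique(scores)) < 2:
        raise ValueError("threshold sweep requires at least two distinct scores")
    thresholds = np.linspace(scores.min(), scores.max(), n_steps)
    pos_scores = np.sort(scores[labels == direction])
    neg_scores = np.sort(scores[labels != direction])
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    side = "right"  # inclusive: score == threshold meets it
    tp = np.searchsorted(pos_scores, thresholds, side=side)
    fp = np.searchsorted(neg_scores, thresholds, side=side)
    if op == "ge":
        tp = n_pos - np.searchsorted(pos_scores, thresholds, side="left")
        fp = n_neg - np.searchsorted(neg_scores, thresholds, side="left")
    fn, tn = n_pos - tp, n_neg - fp
    sens = np.divide(tp, n_pos, out=np.full_like(thresholds, np.nan), where=n_pos > 0)
    spec_ = np.divide(tn, n_neg, out=np.full_like(thresholds, np.nan), where=n_neg > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = sens / (1.0 - spec_)
    defined = (fp > 0) & (tp + fn > 0)
    return pd.DataFrame({
        "threshold": thresholds, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens, "specificity": spec_, "lr_plus": lr,
        "defined": defined,
    })


def benign_threshold(
    scores, pathogenic_threshold: float, metric: str = "adjusted_ms"
) -> float:
    """Mirror the pathogenic threshold to the benign side of the distribution.

    The benign cut-off sits the same number of standard deviations from the
    mean as the pathogenic one, on the opposite side.  CCR scores are centile
    ranks of a bimodal distribution, so their benign threshold is simply
    100 minus the pathogenic threshold.
    """
    if metric == "ccr":
        return 100.0 - pathogenic_threshold
    arr = np.asarray(scores, dtype=float)
    arr = arr[~np.isnan(arr)]
    mean, sd = float(arr.mean()), float(arr.std(ddof=0))
    if sd == 0:
        raise ValueError("score distribution has zero standard deviation")
    z = (pathogenic_threshold - mean) / sd
    return mean - z * sd
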