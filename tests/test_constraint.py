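"""Adjusted m/s constraint score, metric evaluation and threshold machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metadomain import constraint
from metadomain.transcripts import GENETIC_CODE


def universe_for_codons(codons, observed_consequences=(), protein="P1"):
    """Build an exhaustive 9-per-codon universe for a mini protein.

    ``observed_consequences`` lists (residue_index, consequence, count):
    that many possible SNVs of the class are flagged as observed.
    """
    rows = []
    pos = 1
    for i, codon in enumerate(codons, start=1):
        for j in range(3):
            for alt in "ACGT":
                if alt == codon[j]:
                    continue
                alt_codon = codon[:j] + alt + codon[j + 1:]
                ref_aa, alt_aa = GENETIC_CODE[codon], GENETIC_CODE[alt_codon]
                cons = ("nonsense" if alt_aa == "*"
                        else "synonymous" if alt_aa == ref_aa else "missense")
                rows.append({
                    "chrom": "1", "pos": pos + j, "ref": codon[j], "alt": alt,
                    "protein_id": protein, "residue_index": i,
                    "ref_aa": ref_aa, "alt_aa": alt_aa, "consequence": cons,
                    "observed": False,
                })
        pos += 3
    df = pd.DataFrame(rows)
    for residue, cons, count in observed_consequences:
        idx = df.index[(df["residue_index"] == residue)
                       & (df["consequence"] == cons)][:count]
        df.loc[idx, "observed"] = True
    return df


def mapping_for(protein, residues, family="F1"):
    return pd.DataFrame([
        {"protein_id": protein, "residue_index": r, "family_id": family,
         "column_label": str(i + 1), "is_insertion": False}
        for i, r in enumerate(residues)])


class TestCountPossible:
    @pytest.mark.parametrize("codon,expected", [
        ("TTT", (8, 1, 0)),
        ("TGG", (7, 0, 2)),
        ("CTG", (5, 4, 0)),
    ])
    def test_hand_checked_codons(self, codon, expected):
        c = constraint.count_possible(codon)
        assert (c.missense, c.synonymous, c.nonsense) == expected

    def test_partition_sums_to_nine_for_all_sense_codons(self):
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            if GENETIC_CODE[codon] == "*":
                with pytest.raises(ValueError, match="stop codon"):
                    constraint.count_possible(codon)
                continue
            c = constraint.count_possible(codon)
            assert c.missense + c.synonymous + c.nonsense == 9

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError, match="invalid codon"):
            constraint.count_possible("AXG")


class TestAdjustedMs:
    def test_zero_missense_one_synonymous(self):
        uni = universe_for_codons(["TTT"], [(1, "synonymous", 1)])
        out = constraint.adjusted_ms_scores(uni, mapping_for("P1", [1]))
        assert out["adjusted_ms"].iloc[0] == 0.0

    def test_hand_evaluated_ratio(self):
        # (2/8) / (1/1) = 0.25 for a single TTT codon
        uni = universe_for_codons(["TTT"], [(1, "missense", 2), (1, "synonymous", 1)])
        out = constraint.adjusted_ms_scores(uni, mapping_for("P1", [1]))
        assert out["adjusted_ms"].iloc[0] == pytest.approx(0.25)
        assert out["raw_ms"].iloc[0] == pytest.approx(2.0)

    def test_zero_synonymous_denominator_missing_not_zero(self):
        uni = universe_for_codons(["TTT"], [(1, "missense", 3)])
        out = constraint.adjusted_ms_scores(uni, mapping_for("P1", [1]))
        assert np.isnan(out["adjusted_ms"].iloc[0])

    def test_duplicate_member_same_coordinates_dedup(self):
        # the same genomic locus reached through two transcripts counts once
        uni = universe_for_codons(["TTT", "CTG"],
                                  [(1, "missense", 2), (1, "synonymous", 1),
                                   (2, "synonymous", 2)])
        dup = uni.copy()
        dup["protein_id"] = "P2"
        both = pd.concat([uni, dup], ignore_index=True)
        single = constraint.adjusted_ms_scores(uni, mapping_for("P1", [1, 2]))
        mapping2 = pd.concat([mapping_for("P1", [1, 2]), mapping_for("P2", [1, 2])],
                             ignore_index=True)
        doubled = constraint.adjusted_ms_scores(both, mapping2)
        assert doubled["adjusted_ms"].iloc[0] == pytest.approx(
            single["adjusted_ms"].iloc[0])
        assert doubled["n_positions"].iloc[0] == single["n_positions"].iloc[0]

    def test_member_order_invariant(self):
        uni = universe_for_codons(["TTT", "CTG", "AAA"],
                                  [(1, "missense", 1), (2, "synonymous", 1),
                                   (3, "synonymous", 1)])
        m = mapping_for("P1", [1, 2, 3])
        a = constraint.adjusted_ms_scores(uni, m)
        b = constraint.adjusted_ms_scores(uni, m.iloc[::-1])
        assert a["adjusted_ms"].iloc[0] == pytest.approx(b["adjusted_ms"].iloc[0])

    def test_insertions_excluded(self):
        uni = universe_for_codons(["TTT", "CTG"],
                                  [(1, "synonymous", 1), (2, "missense", 4),
                                   (2, "synonymous", 4)])
        m = mapping_for("P1", [1, 2])
        m.loc[m["residue_index"] == 2, "is_insertion"] = True
        out = constraint.adjusted_ms_scores(uni, m)
        # only the TTT position remains: 0 missense over 1 synonymous
        assert out["adjusted_ms"].iloc[0] == 0.0
        assert out["n_positions"].iloc[0] == 1

    def test_pooled_variant_differs_but_close_under_uniform_obs(self):
        uni = universe_for_codons(["TTT", "CTG"],
                                  [(1, "missense", 2), (1, "synonymous", 1),
                                   (2, "missense", 1), (2, "synonymous", 2)])
        m = mapping_for("P1", [1, 2])
        per_pos = constraint.adjusted_ms_scores(uni, m, per_position=True)
        pooled = constraint.adjusted_ms_scores(uni, m, per_position=False)
        assert per_pos["adjusted_ms"].iloc[0] > 0
        assert pooled["adjusted_ms"].iloc[0] > 0


class TestEvaluateMetric:
    def scored(self):
        return pd.DataFrame({
            "label": ["pathogenic", "benign", "pathogenic", "benign"],
            "score": [0.30, 0.30, 0.40, np.nan],
        })

    def test_pathogenic_threshold_le(self):
        spec = constraint.MetricSpec("adjusted_ms", pathogenic_threshold=0.34,
                                     pathogenic_op="le")
        table, n_unscored = constraint.evaluate_metric(self.scored(), spec)
        assert (table.tp, table.fp, table.fn, table.tn) == (1, 1, 1, 1)
        assert n_unscored == 1

    def test_totals_conserved(self):
        spec = constraint.MetricSpec("adjusted_ms", pathogenic_threshold=0.34)
        table, _ = constraint.evaluate_metric(self.scored(), spec)
        assert table.tp + table.fn == 2
        assert table.tn + table.fp == 2

    def test_missing_direction_threshold_rejected(self):
        spec = constraint.MetricSpec("adjusted_ms", pathogenic_threshold=0.34)
        with pytest.raises(ValueError, match="benign threshold"):
            constraint.evaluate_metric(self.scored(), spec, "benign")

    def test_same_comparison_direction_rejected(self):
        with pytest.raises(ValueError, match="oppose"):
            constraint.MetricSpec("x", pathogenic_threshold=1.0,
                                  pathogenic_op="le",
                                  benign_threshold=2.0, benign_op="le")

    def test_high_is_constrained_metric(self):
        spec = constraint.MetricSpec("missense_z", pathogenic_threshold=3.09,
                                     pathogenic_op="ge")
        df = pd.DataFrame({"label": ["pathogenic", "benign"],
                           "score": [3.09, 1.0]})
        table, _ = constraint.evaluate_metric(df, spec)
        assert (table.tp, table.tn) == (1, 1)  # boundary inclusive


class TestThresholdSweep:
    def test_three_steps_linspace(self):
        df = pd.DataFrame({"label": ["pathogenic", "benign"], "score": [0.0, 1.0]})
        sweep = constraint.threshold_sweep(df, n_steps=3)
        assert sweep["threshold"].tolist() == [0.0, 0.5, 1.0]

    def test_endpoints_are_min_and_max(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "label": rng.choice(["pathogenic", "benign"], size=40),
            "score": rng.normal(size=40)})
        sweep = constraint.threshold_sweep(df, n_steps=1000)
        assert sweep["threshold"].iloc[0] == pytest.approx(df["score"].min())
        assert sweep["threshold"].iloc[-1] == pytest.approx(df["score"].max())

    def test_separable_scores_decreasing_lr(self):
        # all pathogenic below all benign (low = constrained)
        df = pd.DataFrame({
            "label": ["pathogenic"] * 5 + ["benign"] * 5,
            "score": [0.0, 0.1, 0.2, 0.3, 0.4, 1.0, 1.1, 1.2, 1.3, 1.4]})
        sweep = constraint.threshold_sweep(df, n_steps=15)
        defined = sweep[sweep["defined"]]
        assert (np.diff(defined["lr_plus"]) <= 1e-12).all()
        low = sweep[sweep["threshold"] < 1.0]
        assert not low["defined"].any()  # fp == 0 below all benign scores

    def test_shuffled_labels_give_lr_near_one(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "label": rng.permutation(["pathogenic"] * 500 + ["benign"] * 500),
            "score": rng.normal(size=1000)})
        sweep = constraint.threshold_sweep(df, n_steps=11)
        mid = sweep[(sweep["sensitivity"] > 0.2) & (sweep["sensitivity"] < 0.8)]
        assert np.abs(np.log(mid["lr_plus"])).max() < np.log(1.5)

    def test_identical_scores_rejected(self):
        df = pd.DataFrame({"label": ["pathogenic", "benign"], "score": [1.0, 1.0]})
        with pytest.raises(ValueError, match="distinct"):
            constraint.threshold_sweep(df)


class TestBenignThreshold:
    def test_mirror_arithmetic(self):
        scores = np.array([0.4, 1.0, 1.6])  # mean 1.0, sd ~0.49
        sd = scores.std()
        got = constraint.benign_threshold(scores, 0.34)
        z = (0.34 - 1.0) / sd
        assert got == pytest.approx(1.0 - z * sd)

    def test_hand_example(self):
        # mean 1.0, sd 0.3: pathogenic 0.34 mirrors to 1.66
        rng = np.random.default_rng(0)
        scores = rng.normal(1.0, 0.3, size=200000)
        got = constraint.benign_threshold(scores, 0.34)
        assert got == pytest.approx(1.66, abs=0.01)

    def test_ccr_hundred_minus_rule(self):
        assert constraint.benign_threshold([1, 2, 3], 95.0, metric="ccr") == 5.0

    def test_threshold_at_mean_maps_to_mean(self):
        scores = np.array([0.5, 1.0, 1.5])
        assert constraint.benign_threshold(scores, 1.0) == pytest.approx(1.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="standard deviation"):
            constraint.benign_threshold([1.0, 1.0], 0.5)
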