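"""Co-localisation evidence: position assignment, PM5 variants, cascade."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_toy_dataset
from _oracles import oracle_meta, oracle_standard

from metadomain import pm5
from metadomain.evaluation import compute_metrics


class TestSummarizePosition:
    @pytest.mark.parametrize("rule", ["no_conflict", "majority"])
    def test_pure_pathogenic(self, rule):
        s = pm5.summarize_position(["pathogenic", "pathogenic"], rule)
        assert s.assignment == "pathogenic"
        assert (s.n_pathogenic, s.n_benign) == (2, 0)

    def test_mixed_depends_on_rule(self):
        labels = ["pathogenic", "pathogenic", "benign"]
        assert pm5.summarize_position(labels, "no_conflict").assignment == "conflicting"
        assert pm5.summarize_position(labels, "majority").assignment == "pathogenic"

    def test_majority_tie_is_conflicting(self):
        assert pm5.summarize_position(
            ["pathogenic", "benign"], "majority").assignment == "conflicting"

    def test_single_variant_unique(self):
        assert pm5.summarize_position(["benign"]).assignment == "unique"

    def test_empty(self):
        assert pm5.summarize_position([]).assignment == "empty"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            pm5.summarize_position(["pathogenic"], "plurality")

    def test_rules_agree_on_pure_multisets(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            labels = [["pathogenic", "benign"][rng.integers(2)]] * int(rng.integers(0, 6))
            a = pm5.summarize_position(labels, "no_conflict").assignment
            b = pm5.summarize_position(labels, "majority").assignment
            assert a == b


def make_dataset(rows):
    """rows: (protein, residue, ref_aa, alt_aa, label)"""
    return pd.DataFrame([
        {"chrom": "1", "pos": i + 1, "ref": "A", "alt": "C",
         "protein_id": p, "residue_index": r, "ref_aa": ra, "alt_aa": aa,
         "label": lab}
        for i, (p, r, ra, aa, lab) in enumerate(rows)])


def make_mapping(entries):
    """entries: (protein, residue, column_label)"""
    return pd.DataFrame([
        {"protein_id": p, "residue_index": r, "family_id": "F1",
         "column_label": str(c), "is_insertion": False}
        for p, r, c in entries])


class TestStandardPm5:
    def test_co_localised_pathogenic_gives_strong_tp(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic"),
                           ("P1", 7, "R", "W", "pathogenic")])
        out = pm5.classify_standard_pm5(ds.iloc[0], ds)
        assert out.criterion == "PM5_same_protein"
        assert out.strength == "strong"
        assert out.role == "TP"

    def test_unique_variant_is_fn(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic"),
                           ("P2", 3, "K", "E", "benign")])
        out = pm5.classify_standard_pm5(ds.iloc[0], ds)
        assert (out.criterion, out.role) == ("none", "FN")

    def test_benign_query_with_pathogenic_neighbour_is_fp(self):
        ds = make_dataset([("P1", 7, "R", "Q", "benign"),
                           ("P1", 7, "R", "W", "pathogenic")])
        assert pm5.classify_standard_pm5(ds.iloc[0], ds).role == "FP"

    def test_same_amino_acid_change_not_different_variant(self):
        # two genomic variants producing the identical substitution do not
        # count as a "different" missense change
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic"),
                           ("P1", 7, "R", "Q", "pathogenic")])
        assert pm5.classify_standard_pm5(ds.iloc[0], ds).criterion == "none"

    def test_mixed_co_localised_set_negative(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic"),
                           ("P1", 7, "R", "W", "pathogenic"),
                           ("P1", 7, "R", "L", "benign")])
        assert pm5.classify_standard_pm5(ds.iloc[0], ds).role == "FN"

    def test_benign_mirror(self):
        ds = make_dataset([("P1", 7, "R", "Q", "benign"),
                           ("P1", 7, "R", "W", "benign"),
                           ("P2", 2, "A", "V", "pathogenic")])
        out = pm5.classify_benign_pm5(ds.iloc[0], ds)
        assert out.criterion == "PM5_benign_same_protein"
        assert out.role == "TP"
        assert pm5.classify_benign_pm5(ds.iloc[2], ds).role == "TN"

    def test_absent_query_rejected(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic")])
        ghost = ds.iloc[0].copy()
        ghost["pos"] = 999
        with pytest.raises(ValueError, match="absent"):
            pm5.classify_standard_pm5(ghost, ds)


class TestMetaPm5:
    def test_cross_protein_evidence_moderate(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic"),
                           ("P2", 3, "R", "W", "pathogenic"),
                           ("P3", 5, "R", "L", "pathogenic")])
        mapping = make_mapping([("P1", 7, 4), ("P2", 3, 4), ("P3", 5, 4)])
        out = pm5.classify_meta_pm5(ds.iloc[0], ds, mapping)
        assert (out.criterion, out.strength, out.role) == ("PM5_meta", "moderate", "TP")

    def test_lone_variant_at_meta_position_unique_fn(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic")])
        mapping = make_mapping([("P1", 7, 4)])
        out = pm5.classify_meta_pm5(ds.iloc[0], ds, mapping)
        assert (out.criterion, out.role) == ("none", "FN")

    def test_rule_changes_mixed_assignment(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic"),
                           ("P2", 3, "R", "W", "pathogenic"),
                           ("P3", 5, "R", "L", "benign")])
        mapping = make_mapping([("P1", 7, 4), ("P2", 3, 4), ("P3", 5, 4)])
        assert pm5.classify_meta_pm5(ds.iloc[0], ds, mapping, "no_conflict").role == "FN"
        assert pm5.classify_meta_pm5(ds.iloc[0], ds, mapping, "majority").role == "TP"

    def test_out_of_domain_flagged(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic")])
        mapping = make_mapping([("P9", 1, 1)])
        out = pm5.classify_meta_pm5(ds.iloc[0], ds, mapping)
        assert out.in_domain is False
        assert out.criterion == "none"

    def test_leave_one_out_weakens_pairs(self):
        ds = make_dataset([("P1", 7, "R", "Q", "pathogenic"),
                           ("P2", 3, "R", "W", "pathogenic")])
        mapping = make_mapping([("P1", 7, 4), ("P2", 3, 4)])
        incl = pm5.evaluate_meta(ds, mapping)
        loo = pm5.evaluate_meta(ds, mapping, leave_one_out=True)
        assert incl["positive"].all()
        assert not loo["positive"].any()  # each residual set is a singleton


class TestCascade:
    def setup_method(self):
        self.ds = make_dataset([
            ("P1", 7, "R", "Q", "pathogenic"),   # same-protein evidence
            ("P1", 7, "R", "W", "pathogenic"),
            ("P2", 3, "R", "L", "pathogenic"),   # only meta evidence (col 4)
            ("P3", 9, "K", "E", "pathogenic"),   # nothing, out of domain
        ])
        self.mapping = make_mapping([("P1", 7, 4), ("P2", 3, 4)])

    def test_standard_wins_before_meta(self):
        out = pm5.cascade_pm5(self.ds.iloc[0], self.ds, self.mapping)
        assert (out.criterion, out.strength) == ("PM5_same_protein", "strong")

    def test_meta_fallback_moderate(self):
        out = pm5.cascade_pm5(self.ds.iloc[2], self.ds, self.mapping)
        assert (out.criterion, out.strength) == ("PM5_meta", "moderate")

    def test_neither_gives_none(self):
        out = pm5.cascade_pm5(self.ds.iloc[3], self.ds, self.mapping)
        assert (out.criterion, out.strength, out.role) == ("none", "none", "FN")

    def test_cascade_sensitivity_dominates_standard(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            ds, mapping = random_toy_dataset(rng)
            std = pm5.contingency(ds, pm5.evaluate_standard(ds), "pathogenic")
            cas = pm5.contingency(
                ds, pm5.evaluate_cascade(ds, mapping), "pathogenic")
            if std.tp + std.fn == 0 or std.tn + std.fp == 0:
                continue
            assert (compute_metrics(cas).sensitivity
                    >= compute_metrics(std).sensitivity)


class TestConservationAndOracle:
    @pytest.mark.parametrize("direction", ["pathogenic", "benign"])
    def test_contingency_conserves_totals(self, direction):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ds, mapping = random_toy_dataset(rng)
            for out in (pm5.evaluate_standard(ds, direction),
                        pm5.evaluate_meta(ds, mapping, "majority", direction)):
                t = pm5.contingency(ds, out, direction)
                assert t.tp + t.fn == (ds["label"] == direction).sum()
                assert t.tn + t.fp == (ds["label"] != direction).sum()

    @pytest.mark.parametrize("direction", ["pathogenic", "benign"])
    @pytest.mark.parametrize("rule", ["no_conflict", "majority"])
    def test_matches_brute_force_oracle(self, rule, direction):
        rng = np.random.default_rng(13)
        for _ in range(8):
            ds, mapping = random_toy_dataset(rng, n_variants=20)
            got = pm5.contingency(ds, pm5.evaluate_standard(ds, direction), direction)
            want = oracle_standard(ds, direction)
            assert (got.tp, got.fp, got.fn, got.tn) == (
                want.tp, want.fp, want.fn, want.tn)
            stratum = ds.merge(mapping[["protein_id", "residue_index"]].drop_duplicates(),
                               on=["protein_id", "residue_index"])
            if stratum.empty:
                continue
            got = pm5.contingency(
                stratum, pm5.evaluate_meta(stratum, mapping, rule, direction), direction)
            want = oracle_meta(stratum, mapping, rule, direction)
            assert (got.tp, got.fp, got.fn, got.tn, got.n_unique) == (
                want.tp, want.fp, want.fn, want.tn, want.n_unique)
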