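"""Information score, count normalization and prediction mechanics."""

import math
from fractions import Fraction

import numpy as np
import pytest

from rrmbind import (BindingSpecificityModel, BindingSpecificityResults,
                     ComplexEntry, InputError, information_score)
from rrmbind.binding_modes import RnaMsa
from rrmbind.alignment import AlignedRRM
from rrmbind.model import ContactCountTable


def manual_msa(rows, core_positions):
    msa = RnaMsa(rows=dict(rows), offsets={k: 0 for k in rows}, medoid=None)
    msa.core_positions = core_positions
    return msa


def entry(eid, uid, aligned, rna, contact_map):
    return ComplexEntry(entry_id=eid, uniprot_id=uid, aligned_seq=aligned,
                        rna_seq=rna, contact_map=contact_map)


class TestInformationScore:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_literal_transcription(self, seed):
        """Random count tables: agree with an exact-arithmetic oracle."""
        rng = np.random.default_rng(seed)
        f_n_r = {}
        for n in "ACGU":
            for r in "KRE":
                c = int(rng.integers(0, 6))
                if c:
                    f_n_r[(n, r)] = float(c)
        f_n = {n: float(rng.integers(1, 9)) for n in "ACGU"}
        ct = ContactCountTable(column=0, position=1, f_n_r=f_n_r, f_n=f_n)
        for n in "ACGU":
            for r in "KRE":
                got = information_score(ct, r, n)
                fnr = Fraction(f_n_r.get((n, r), 0))
                fnotr = sum((Fraction(v) for (n2, r2), v in f_n_r.items()
                             if r2 == r and n2 != n), Fraction(0))
                fn = Fraction(f_n[n])
                fnotn = sum(Fraction(v) for k, v in f_n.items()) - fn
                if min(fnr, fnotr, fn, fnotn) <= 0:
                    assert got is None
                else:
                    expected = (math.log(fnr) - math.log(fnotr)
                                + math.log(fnotn) - math.log(fn))
                    assert got == pytest.approx(expected, rel=1e-12,
                                                abs=1e-12)

    def test_no_preference_scores_zero(self):
        # every nucleotide contacts K equally and marginals are uniform
        ct = ContactCountTable(
            column=0, position=1,
            f_n_r={(n, "K"): 1.0 for n in "ACGU"},
            f_n={n: 2.0 for n in "ACGU"})
        for n in "ACGU":
            assert information_score(ct, "K", n) == pytest.approx(0.0,
                                                                  abs=1e-14)

    def test_pseudocount_rescues_zero_cells(self):
        ct = ContactCountTable(column=0, position=1,
                               f_n_r={("G", "K"): 2.0},
                               f_n={"G": 2.0, "A": 1.0})
        assert information_score(ct, "K", "G") is None
        assert information_score(ct, "K", "G",
                                 pseudocount=0.5) is not None

    def test_log_base_conversion(self):
        ct = ContactCountTable(column=0, position=1,
                               f_n_r={("G", "K"): 4.0, ("A", "K"): 1.0},
                               f_n={"G": 4.0, "A": 2.0})
        nat = information_score(ct, "K", "G")
        base2 = information_score(ct, "K", "G", log_base=2.0)
        assert base2 == pytest.approx(nat / math.log(2), rel=1e-12)


class TestUnbiasedCounts:
    def make_model(self, entries):
        rows = {}
        for e in entries:
            rows[e.entry_id] = e.rna_seq
        msa = manual_msa(rows, core_positions=[0])
        return BindingSpecificityModel(entries, msa, prevalence=0.0)

    def test_eight_of_ten_structures_contribute_point_eight(self):
        entries = []
        for s in range(10):
            has = s < 8
            entries.append(entry(f"e{s}", "U1", "KVKVKV", "A",
                                 {0: {2} if has else {4}}))
        model = self.make_model(entries)
        ct = model._count_table(2, 1, frozenset())
        assert ct.f_n_r[("A", "K")] == pytest.approx(0.8)

    def test_hand_computed_fractions_across_groups(self):
        # groups of 1, 2 and 4 structures; contact at column 2 present in
        # 1/1, 1/2 and 3/4 respectively -> 1 + 0.5 + 0.75 = 2.25
        entries = [entry("a0", "U1", "KVKVKV", "A", {0: {2}})]
        entries += [entry(f"b{s}", "U2", "KVKVKV", "A",
                          {0: {2} if s == 0 else {4}}) for s in range(2)]
        entries += [entry(f"c{s}", "U3", "KVKVKV", "A",
                          {0: {2} if s < 3 else {4}}) for s in range(4)]
        model = self.make_model(entries)
        ct = model._count_table(2, 1, frozenset())
        assert ct.f_n_r[("A", "K")] == pytest.approx(2.25)
        # marginal: every structure shows A at the position, one per group
        assert ct.f_n["A"] == pytest.approx(3.0)

    def test_single_structure_groups_equal_raw_counts(self):
        entries = [entry(f"e{i}", f"U{i}", "KVKVKV", "ACGU"[i % 4],
                         {0: {2}}) for i in range(6)]
        norm = self.make_model(entries)._count_table(2, 1, frozenset())
        raw_model = BindingSpecificityModel(
            entries, manual_msa({e.entry_id: e.rna_seq for e in entries},
                                [0]),
            prevalence=0.0, normalize="raw")
        raw = raw_model._count_table(2, 1, frozenset())
        assert norm.f_n_r == raw.f_n_r
        assert norm.f_n == raw.f_n

    def test_duplicating_one_uniprot_leaves_counts_unchanged(self):
        entries = [entry("a0", "U1", "KVKVKV", "A", {0: {2}}),
                   entry("b0", "U2", "RVRVRV", "G", {0: {2}}),
                   entry("b1", "U2", "RVRVRV", "C", {0: {2}})]
        base = self.make_model(entries)._count_table(2, 1, frozenset())
        doubled = entries + [
            entry("b0x", "U2", "RVRVRV", "G", {0: {2}}),
            entry("b1x", "U2", "RVRVRV", "C", {0: {2}})]
        dup = self.make_model(doubled)._count_table(2, 1, frozenset())
        for k, v in base.f_n_r.items():
            assert dup.f_n_r[k] == pytest.approx(v, rel=1e-12)
        for k, v in base.f_n.items():
            assert dup.f_n[k] == pytest.approx(v, rel=1e-12)


class TestKeyInteractionSelection:
    def test_prevalence_boundary_is_inclusive(self):
        # 1 of 5 proteins = 20% >= 20% threshold: kept
        entries = [entry(f"e{i}", f"U{i}", "KVKVKV", "A",
                         {0: {2} if i == 0 else {4}}) for i in range(5)]
        msa = manual_msa({e.entry_id: e.rna_seq for e in entries}, [0])
        model = BindingSpecificityModel(entries, msa, prevalence=0.20)
        assert (2, 1) in model.key_interactions
        assert (4, 1) in model.key_interactions

    def test_prevalence_zero_keeps_every_observed_pair(self, pipeline_result):
        entries = pipeline_result.entries
        model = BindingSpecificityModel(entries, pipeline_result.rna_msa,
                                        prevalence=0.0)
        observed = set()
        for e in entries:
            view = model._views[e.entry_id]
            for pos, (_, cols) in view.items():
                observed.update((c, pos) for c in cols)
        assert set(model.key_interactions) == observed

    def test_sorted_by_position_then_column(self, fitted):
        ks = fitted.key_interactions
        assert ks == sorted(ks, key=lambda t: (t[1], t[0]))


class TestTraining:
    def test_entry_order_does_not_change_the_model(self, pipeline_result):
        entries = pipeline_result.entries
        msa = pipeline_result.rna_msa
        a = BindingSpecificityModel(entries, msa).fit()
        b = BindingSpecificityModel(list(reversed(entries)), msa).fit()
        assert set(a.tables) == set(b.tables)
        for key in a.tables:
            ta, tb = a.tables[key], b.tables[key]
            assert list(ta.scores.index) == list(tb.scores.index)
            assert np.allclose(ta.scores.to_numpy(), tb.scores.to_numpy(),
                               rtol=1e-12, equal_nan=True)

    def test_planted_preference_recovered(self, fitted, planted_fixture):
        _, _, truth = planted_fixture
        for cell in truth.planted_cells:
            s = fitted.cell_score(cell["column"], cell["position"],
                                  cell["residue"], cell["nucleotide"])
            assert s is not None and s > 0
            for other in "ACGU":
                if other == cell["nucleotide"]:
                    continue
                s_other = fitted.cell_score(cell["column"], cell["position"],
                                            cell["residue"], other)
                if s_other is not None:
                    assert s > s_other

    def test_exclusion_removes_an_entrys_evidence(self):
        # the excluded entry is the only carrier of G at the position:
        # without it, G disappears from the marginal entirely
        entries = [entry("a0", "U1", "KVKVKV", "G", {0: {2}}),
                   entry("b0", "U2", "RVRVRV", "A", {0: {2}}),
                   entry("c0", "U3", "EVEVEV", "C", {0: {2}})]
        msa = manual_msa({e.entry_id: e.rna_seq for e in entries}, [0])
        model = BindingSpecificityModel(entries, msa, prevalence=0.0)
        full = model._count_table(2, 1, frozenset())
        without = model._count_table(2, 1, frozenset({"a0"}))
        assert "G" in full.f_n
        assert "G" not in without.f_n
        assert ("G", "K") not in without.f_n_r

    def test_excluding_everything_rejected(self, pipeline_result):
        model = pipeline_result.model
        with pytest.raises(InputError):
            model.fit(exclude={e.entry_id for e in model.entries})


class TestScorePair:
    def test_raw_score_is_mean_of_breakdown(self, fitted, pipeline_result):
        e = pipeline_result.entries[0]
        pred = fitted.score_pair(e, "ACGUA")
        assert pred.n_scored == len(pred.breakdown)
        if pred.breakdown:
            mean = sum(b["score"] for b in pred.breakdown) / pred.n_scored
            assert pred.raw_score == pytest.approx(mean, abs=1e-12)

    def test_short_windows_anchor_three_prime(self, fitted, pipeline_result):
        e = pipeline_result.entries[0]
        pred = fitted.score_pair(e, "ACG")
        assert pred.start_position == 3
        assert all(3 <= b["position"] <= 5 for b in pred.breakdown)

    def test_window_validation(self, fitted, pipeline_result):
        e = pipeline_result.entries[0]
        with pytest.raises(InputError):
            fitted.score_pair(e, "AC")          # too short
        with pytest.raises(InputError):
            fitted.score_pair(e, "ACGUAC")      # too long
        with pytest.raises(InputError):
            fitted.score_pair(e, "ACGXN")       # bad characters
        with pytest.raises(InputError):
            fitted.score_pair(e, "ACG", start_position=4)  # falls off 3' end

    def test_report_offset_only_shifts_reported(self, fitted,
                                                pipeline_result):
        e = pipeline_result.entries[0]
        plain = fitted.score_pair(e, "ACGUA")
        shifted = fitted.score_pair(e, "ACGUA", report_offset=0.89)
        assert shifted.raw_score == plain.raw_score
        assert shifted.reported_score == pytest.approx(
            plain.raw_score + 0.89)

    def test_unobserved_residue_is_skipped_not_scored(self, fitted):
        key = fitted.key_interactions[0]
        table = fitted.tables[key]
        unseen = next(r for r in "WHMPY" if r not in table.scores.index)
        lone = AlignedRRM(entry_id="w", sequence=unseen,
                          n_columns=key[0] + 1,
                          column_of_residue={0: key[0]})
        pred = fitted.score_pair(lone, "ACGUA")
        # the unseen residue is "no data", everything else is a gap:
        # nothing gets a number, and the skips are all accounted for
        assert pred.n_scored == 0
        assert pred.n_skipped == len(fitted.key_interactions)
        assert math.isnan(pred.raw_score)


class TestScan:
    def test_rna_equal_to_window_gives_one_prediction(self, fitted,
                                                      pipeline_result):
        e = pipeline_result.entries[0]
        preds = fitted.scan(e, "ACGUA", window=5)
        assert len(preds) == 1 and preds[0].rna_offset == 0

    def test_matches_exhaustive_window_enumeration(self, fitted,
                                                   pipeline_result):
        e = pipeline_result.entries[0]
        rna = "ACGUAGGCAUCG"
        preds = fitted.scan(e, rna, window=5)
        assert len(preds) == len(rna) - 4
        for p in preds:
            direct = fitted.score_pair(e, rna[p.rna_offset:p.rna_offset + 5])
            assert p.raw_score == pytest.approx(direct.raw_score, nan_ok=True)
        best = fitted.best_window(preds)
        finite = [p for p in preds if not math.isnan(p.raw_score)]
        assert best.raw_score == max(p.raw_score for p in finite)
        # 5'-most on ties
        top = [p for p in finite if p.raw_score == best.raw_score]
        assert best.rna_offset == min(p.rna_offset for p in top)

    def test_too_short_rna_rejected(self, fitted, pipeline_result):
        with pytest.raises(InputError):
            fitted.scan(pipeline_result.entries[0], "ACG", window=5)


class TestMutationEffect:
    @staticmethod
    def aligned_from_entry(e):
        return AlignedRRM.from_gapped(e.entry_id, e.aligned_seq)

    def test_identity_mutation_changes_nothing(self, fitted,
                                               pipeline_result):
        rrm = self.aligned_from_entry(pipeline_result.entries[0])
        eff = fitted.mutation_effect(rrm, (0, rrm.sequence[0]), "ACGUA")
        assert eff.deltas == []
        assert eff.after.raw_score == pytest.approx(eff.before.raw_score,
                                                    nan_ok=True)

    def test_delta_is_cell_difference_over_n_scored(self, fitted,
                                                    planted_fixture,
                                                    pipeline_result):
        """A one-column substitution moves the mean by (new-old)/n."""
        _, _, truth = planted_fixture
        cell = truth.planted_cells[0]          # K at β1–1 prefers G at pos 4
        col, pos = cell["column"], cell["position"]
        window = "AAA" + cell["nucleotide"] + "A"  # planted nuc at pos 4
        table = fitted.tables[(col, pos)]
        candidates = [r for r in table.scores.index
                      if not np.isnan(table.scores.at[r,
                                                      cell["nucleotide"]])]
        found = False
        for e in pipeline_result.entries:
            rrm = self.aligned_from_entry(e)
            idx = rrm.residue_of_column.get(col)
            if idx is None or rrm.sequence[idx] not in candidates:
                continue
            for new in candidates:
                if new == rrm.sequence[idx]:
                    continue
                eff = fitted.mutation_effect(rrm, (idx, new), window)
                if (eff.before.n_scored != eff.after.n_scored
                        or math.isnan(eff.before.raw_score)):
                    continue
                old_cell = fitted.cell_score(col, pos, rrm.sequence[idx],
                                             cell["nucleotide"])
                new_cell = fitted.cell_score(col, pos, new,
                                             cell["nucleotide"])
                expected = (new_cell - old_cell) / eff.before.n_scored
                assert (eff.after.raw_score - eff.before.raw_score
                        == pytest.approx(expected, abs=1e-12))
                found = True
                break
            if found:
                break
        assert found, "fixture should offer at least one clean substitution"

    def test_non_key_column_flagged_with_zero_delta(self, fitted,
                                                    pipeline_result):
        rrm = self.aligned_from_entry(pipeline_result.entries[0])
        key_cols = {c for c, _ in fitted.key_interactions}
        idx = next(i for i, c in rrm.column_of_residue.items()
                   if c not in key_cols)
        with pytest.warns(UserWarning, match="not at a key"):
            eff = fitted.mutation_effect(rrm, (idx, "W"), "ACGUA")
        assert not eff.at_key_column
        assert eff.deltas == []

    def test_string_substitution_checks_original_residue(self, fitted,
                                                         pipeline_result):
        rrm = self.aligned_from_entry(pipeline_result.entries[0])
        wrong = "W" if rrm.sequence[0] != "W" else "K"
        with pytest.raises(InputError):
            fitted.mutation_effect(rrm, f"{wrong}1K", "ACGUA")


class TestSerialization:
    def test_json_round_trip_scores_identically(self, fitted,
                                                pipeline_result, tmp_path):
        path = tmp_path / "model.json"
        fitted.to_json(path)
        back = BindingSpecificityResults.from_json(path)
        assert back.key_interactions == fitted.key_interactions
        e = pipeline_result.entries[0]
        a = fitted.score_pair(e, "ACGUA")
        b = back.score_pair(e, "ACGUA")
        assert b.raw_score == pytest.approx(a.raw_score, nan_ok=True)
        assert b.n_scored == a.n_scored
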