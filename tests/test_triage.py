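"""The four false-positive rules, gates, idempotence and sweep monotonicity."""

import dataclasses

import pytest

from svatk.chem import mz_from_mass, peptide_mass
from svatk.digestion import TRYPSIN, ProteinRecord
from svatk.psm_io import PSMRecord, VariantCall, make_config
from svatk.triage import (
    apply_gates,
    parse_comment,
    rule_below_quant_limit,
    rule_orthogonal_redundant,
    rule_semi_nonKR,
    rule_terminal_residue,
    threshold_sweep,
    triage_run,
)

CFG = make_config("high_res")

#                     1         2
#            123456789012345678901234
PROTEIN = ProteinRecord("mab1_LC", "LC", "SAPLKGAVTWDNKSGPLKCATMYR")


def _psm(peptide, start, end, variant, enzyme="trypsin", score=300.0,
         ppm=0.5, psm_id="p1", area=1e6):
    charge = 2
    mz_theo = mz_from_mass(peptide_mass(peptide), charge)
    mz_obs = mz_theo * (1 + ppm / 1e6)
    return PSMRecord(
        psm_id=psm_id, peptide=peptide, protein_id=PROTEIN.id, start=start,
        end=end, enzyme=enzyme, charge=charge, mz_observed=mz_obs,
        mz_theoretical=mz_theo,
        precursor_ppm=1e6 * (mz_obs - mz_theo) / mz_theo, score=score,
        engine="byonic-like", rt=30.0, xic_area=area, variant=variant)


class TestRuleSemiNonKR:
    def test_uninvolved_mid_peptide_variant_triggers(self):
        # GAVTWDNK is fully tryptic (6-13); GAVTWDN (6-12) is semi.
        v = VariantCall(PROTEIN.id, 8, "V", "A", "LC")
        psm = _psm("GAATWDN", 6, 12, v)
        assert rule_semi_nonKR(psm, PROTEIN, TRYPSIN)

    def test_lysine_involved_variant_does_not_trigger(self):
        v = VariantCall(PROTEIN.id, 13, "K", "N", "LC")
        psm = _psm("AVTWDNN", 7, 13, v)  # N-side nonspecific junction
        assert rule_semi_nonKR(psm, PROTEIN, TRYPSIN) is None

    def test_variant_at_nonspecific_junction_does_not_trigger(self):
        v = VariantCall(PROTEIN.id, 7, "A", "V", "LC")
        psm = _psm("VVTWDNK", 7, 13, v)  # junction at position 7
        assert rule_semi_nonKR(psm, PROTEIN, TRYPSIN) is None

    def test_fully_tryptic_peptide_never_triggers(self):
        v = VariantCall(PROTEIN.id, 8, "V", "A", "LC")
        psm = _psm("GAATWDNK", 6, 13, v)
        assert rule_semi_nonKR(psm, PROTEIN, TRYPSIN) is None

    def test_non_tryptic_enzyme_out_of_scope(self):
        v = VariantCall(PROTEIN.id, 8, "V", "A", "LC")
        psm = _psm("GAATWDN", 6, 12, v, enzyme="thermolysin")
        assert rule_semi_nonKR(psm, PROTEIN, TRYPSIN) is None


class TestRuleTerminalResidue:
    def test_alanine_shift_with_terminal_alanine_triggers(self):
        # G7A... shift +71.0371 matches Ala; peptide SAPLK has A at position 2.
        v = VariantCall(PROTEIN.id, 3, "P", "+71.0371", "LC")
        psm = _psm("SAPLK", 1, 5, v)
        hit = rule_terminal_residue(psm, CFG)
        assert hit and "R2_terminal_residue" in hit

    def test_58_0055_matches_no_residue(self):
        v = VariantCall(PROTEIN.id, 2, "A", "E", "LC")
        psm = _psm("SEPLK", 1, 5, v)
        assert rule_terminal_residue(psm, CFG) is None

    def test_matching_residue_absent_from_terminal_window(self):
        v = VariantCall(PROTEIN.id, 16, "P", "+71.0371", "LC")
        psm = _psm("SGPLK", 14, 18, v)  # no A anywhere
        assert rule_terminal_residue(psm, CFG) is None

    def test_loss_shift_only_flags_with_both_signs(self):
        v = VariantCall(PROTEIN.id, 3, "P", "-71.0371", "LC")
        psm = _psm("SAPLK", 1, 5, v)
        assert rule_terminal_residue(psm, CFG) is None
        both = dataclasses.replace(CFG, terminal_rule_both_signs=True)
        assert rule_terminal_residue(psm, both)


@pytest.mark.parametrize("pct,expected", [
    (0.1, True),   # below the 0.2% limit
    (0.2, False),  # at the limit: kept
    (0.5, False),
])
def test_rule_below_quant_limit(pct, expected):
    assert bool(rule_below_quant_limit(pct, CFG)) is expected


class TestRuleOrthogonalRedundant:
    def _site_psms(self, trypsin_score):
        v = VariantCall(PROTEIN.id, 8, "V", "A", "LC")
        return [
            _psm("GAATWDNK", 6, 13, v, score=trypsin_score, psm_id="t1"),
            _psm("AATWD", 7, 11, v, enzyme="thermolysin", score=260.0,
                 psm_id="o1"),
        ]

    def test_confident_tryptic_coverage_flags_orthogonal_psm(self):
        triggered = rule_orthogonal_redundant(self._site_psms(300.0), CFG)
        assert set(triggered) == {"o1"}

    def test_weak_tryptic_coverage_does_not_flag(self):
        assert rule_orthogonal_redundant(self._site_psms(100.0), CFG) == {}

    def test_orthogonal_only_site_never_flags(self):
        v = VariantCall(PROTEIN.id, 8, "V", "A", "LC")
        psms = [_psm("AATWD", 7, 11, v, enzyme="asp-n", psm_id="o1")]
        assert rule_orthogonal_redundant(psms, CFG) == {}


def test_gates_are_strict_on_score_and_inclusive_on_ppm():
    v = VariantCall(PROTEIN.id, 8, "V", "A", "LC")
    below = _psm("GAATWDNK", 6, 13, v, score=224.9)
    assert [c.split(":")[0] for c in apply_gates(below, CFG)] == ["G_score"]
    high_ppm = _psm("GAATWDNK", 6, 13, v, ppm=2.1)
    assert [c.split(":")[0] for c in apply_gates(high_ppm, CFG)] == [
        "G_mass_error"]
    boundary = _psm("GAATWDNK", 6, 13, v, score=225.0, ppm=-1.9)
    assert apply_gates(boundary, CFG) == []


def test_triage_run_empty_inputs():
    annotations, summary = triage_run([], {}, {}, CFG)
    assert annotations == []
    assert summary.unique_variant_peptides_before == 0
    assert summary.retained_sites == ()


def test_triage_run_rejects_dangling_protein():
    v = VariantCall("ghost", 8, "V", "A", "LC")
    psm = _psm("GAATWDNK", 6, 13, v)
    psm = dataclasses.replace(psm, protein_id="ghost")
    with pytest.raises(ValueError, match="ghost"):
        triage_run([psm], {PROTEIN.id: PROTEIN}, {}, CFG)


def test_sva7_retention_and_comment_completeness(sva7, sva7_proteins,
                                                 sva7_quants):
    annotations, summary = triage_run(
        sva7.psms, sva7_proteins, sva7_quants, CFG)
    assert len(summary.retained_sites) == 7
    assert set(summary.retained_sites) == sva7.true_sites
    for a in annotations:
        assert (a.status == "false_positive") == bool(a.triggered_rules)
        assert parse_comment(a.comment) == set(a.triggered_rules)


def test_triage_is_idempotent(sva7, sva7_proteins, sva7_quants):
    """Re-running triage on the same inputs changes nothing."""
    first, s1 = triage_run(sva7.psms, sva7_proteins, sva7_quants, CFG)
    second, s2 = triage_run(sva7.psms, sva7_proteins, sva7_quants, CFG)
    assert first == second and s1 == s2


def test_no_true_variant_is_ever_flagged(sva7, sva7_proteins, sva7_quants):
    """Zero false negatives on planted truth at generator defaults."""
    annotations, _ = triage_run(sva7.psms, sva7_proteins, sva7_quants, CFG)
    by_id = {a.psm_id: a for a in annotations}
    for row in sva7.truth:
        if row["klass"] != "true_sv":
            continue
        for pid in row["psm_ids"].split(";"):
            assert by_id[pid].status == "retained"


def test_planted_fp_classes_flagged_by_their_rule(sva7, sva7_proteins,
                                                  sva7_quants):
    annotations, _ = triage_run(sva7.psms, sva7_proteins, sva7_quants, CFG)
    by_id = {a.psm_id: a for a in annotations}
    for row in sva7.truth:
        if not row["expected_rule"]:
            continue
        for pid in row["psm_ids"].split(";"):
            assert row["expected_rule"] in by_id[pid].triggered_rules, row


def test_threshold_sweep_monotone_and_edges(sva7, sva7_proteins, sva7_quants):
    rows = threshold_sweep(
        sva7.psms, sva7_proteins, sva7_quants, CFG,
        [0.0, 200.0, 225.0, 250.0, 300.0, 1e9],
        truth_sites=sva7.true_sites)
    retained = [r["retained_unique_variant_peptides"] for r in rows]
    assert retained == sorted(retained, reverse=True)
    assert rows[-1]["retained_unique_variant_peptides"] == 0
    assert rows[0]["retained_sites"] == 7  # cutoff 0 keeps all true sites


def test_retention_monotone_in_quant_limit_and_ms1_tol(sva7, sva7_proteins,
                                                       sva7_quants):
    def retained(cfg):
        _, s = triage_run(sva7.psms, sva7_proteins, sva7_quants, cfg)
        return s.unique_variant_peptides_after

    by_limit = [retained(dataclasses.replace(CFG, quant_limit_pct=q))
                for q in (0.0, 0.1, 0.2, 0.6, 5.0)]
    assert by_limit == sorted(by_limit, reverse=True)
    by_tol = [retained(dataclasses.replace(CFG, ms1_tol_ppm=t))
              for t in (0.1, 1.0, 2.0, 8.0)]
    assert by_tol == sorted(by_tol)
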