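import numpy as np
import pytest

import nvafsurv as nv
from nvafsurv import conditions as C
from nvafsurv.phenotype import (SurveillanceMode, TriageLabel,
                                apply_exclusions, apply_inclusion,
                                classify_nvaf, concordance_triage, detect_af,
                                phenotype_cohort, phenotype_patient,
                                semisupervised_iterate)
from nvafsurv.simulate import ClinicalNote, Patient
from nvafsurv.terminology import Lexicon, LexiconEntry

S = SurveillanceMode.STRUCTURED
K = SurveillanceMode.COMBINED


def mk_patient(age=70, sex="M", visits=3, notes=("Stable visit.",),
               codes=(), meds=()):
    return Patient(
        patient_id="T1", sex=sex, age=age, race="White",
        structured_codes=[("2014-01-01", "ICD9", c) for c in codes],
        medications=[("2014-01-01", d, cls) for d, cls in meds],
        notes=[ClinicalNote("T1", "2014-01-01", t) for t in notes],
        outpatient_visits=visits)


class TestInclusion:
    def test_age_below_boundary(self):
        assert not apply_inclusion(mk_patient(age=17))

    def test_minimal_qualifying_patient(self):
        assert apply_inclusion(mk_patient(age=18, visits=1))

    def test_no_notes_excluded(self):
        assert not apply_inclusion(mk_patient(age=70, notes=()))

    def test_missing_age_errors(self):
        p = mk_patient()
        p.age = None
        with pytest.raises(ValueError, match="age"):
            apply_inclusion(p)


class TestDetectAf:
    def test_structured_code_found_in_both_modes(self, lex, hier):
        p = mk_patient(codes=("427.31",))
        assert detect_af(p, S, lex, hier) and detect_af(p, K, lex, hier)

    def test_note_only_af(self, lex, hier):
        p = mk_patient(notes=("Patient has atrial fibrillation.",))
        assert not detect_af(p, S, lex, hier)
        assert detect_af(p, K, lex, hier)

    def test_subtype_descendant_detected(self, lex, hier):
        p = mk_patient(notes=("Patient has paroxysmal atrial fibrillation.",))
        assert detect_af(p, K, lex, hier)

    def test_negated_mention_ignored(self, lex, hier):
        p = mk_patient(notes=("No atrial fibrillation.",))
        assert not detect_af(p, K, lex, hier)


class TestExclusions:
    def test_mechanical_valve_code(self, lex, hier):
        p = mk_patient(codes=("V43.3",))
        assert apply_exclusions(p, S, lex, hier) == {"MECHANICAL_VALVE"}

    def test_no_evidence_empty(self, lex, hier):
        assert apply_exclusions(mk_patient(), S, lex, hier) == set()

    def test_pregnancy_and_endocarditis_independent(self, lex, hier):
        p = mk_patient(codes=("V22.2", "421.0"))
        assert apply_exclusions(p, S, lex, hier) == \
            {"PREGNANCY", "ENDOCARDITIS"}

    def test_note_evidence_only_in_combined_mode(self, lex, hier):
        p = mk_patient(notes=("Patient has infective endocarditis.",))
        assert apply_exclusions(p, S, lex, hier) == set()
        assert apply_exclusions(p, K, lex, hier) == {"ENDOCARDITIS"}

    def test_transient_af_requires_temporal_proximity(self, lex, hier):
        near = Patient("T1", "M", 70, "W", outpatient_visits=1,
                       notes=[ClinicalNote("T1", "2014-01-01", "ok")],
                       structured_codes=[("2014-01-01", "ICD9", "427.31"),
                                         ("2014-01-15", "ICD9", "242.90")])
        far = Patient("T1", "M", 70, "W", outpatient_visits=1,
                      notes=[ClinicalNote("T1", "2014-01-01", "ok")],
                      structured_codes=[("2014-01-01", "ICD9", "427.31"),
                                        ("2014-06-01", "ICD9", "242.90")])
        assert "TRANSIENT_REVERSIBLE_AF" in apply_exclusions(near, S, lex,
                                                             hier)
        assert "TRANSIENT_REVERSIBLE_AF" not in apply_exclusions(far, S, lex,
                                                                 hier)

    def test_other_antithrombotic_from_meds(self, lex, hier):
        p = mk_patient(meds=(("clopidogrel", "OTHER_ANTITHROMBOTIC"),))
        assert "OTHER_ANTITHROMBOTIC" in apply_exclusions(p, S, lex, hier)


class TestClassifyNvaf:
    def test_af_without_vhd_or_exclusion(self):
        r = classify_nvaf("P", S, True, True, False, set())
        assert r.nvaf

    def test_vhd_blocks(self):
        r = classify_nvaf("P", S, True, True, True, set())
        assert not r.nvaf and r.vaf

    def test_no_af_never_nvaf(self):
        assert not classify_nvaf("P", S, True, False, False, set()).nvaf

    def test_not_included_clears_downstream(self):
        r = classify_nvaf("P", S, False, True, False, set())
        assert not (r.af or r.nvaf or r.vaf)


class TestTriage:
    @pytest.mark.parametrize("s,c,expected", [
        (True, True, TriageLabel.TRUE_POSITIVE),
        (False, False, TriageLabel.TRUE_NEGATIVE),
        (True, False, TriageLabel.REVIEW),
        (False, True, TriageLabel.REVIEW),
    ])
    def test_mapping_total(self, s, c, expected):
        assert concordance_triage(s, c) is expected


class TestCohortProperties:
    def test_af_mode_dominance(self, small_cohort, lex, hier):
        """Structured AF detection implies combined AF detection."""
        patients, _ = small_cohort
        for p in patients:
            if detect_af(p, S, lex, hier):
                assert detect_af(p, K, lex, hier)

    def test_cascade_conservation(self, small_cohort, lex, hier):
        patients, _ = small_cohort
        df = phenotype_cohort(patients, lex, hier)
        comb = df[df["mode"] == "combined"]
        n = len(patients)
        assert int(comb["included"].sum()) + int((~comb["included"]).sum()) \
            == n
        inc = comb[comb["included"]]
        af_pos = int(inc["af"].sum())
        af_neg = int((~inc["af"]).sum())
        assert af_pos + af_neg == len(inc)
        nvaf = int(inc["nvaf"].sum())
        vaf_or_excluded = int((inc["af"] & ~inc["nvaf"]).sum())
        assert nvaf + vaf_or_excluded == af_pos

    def test_true_cases_never_lost_by_combined(self, small_cohort, lex, hier):
        """Among gold NVAF patients, structured positives are a subset of
        combined positives."""
        patients, gold = small_cohort
        nvaf_ids = set(gold.loc[gold["nvaf"], "patient_id"])
        for p in patients:
            if p.patient_id not in nvaf_ids or not apply_inclusion(p):
                continue
            if phenotype_patient(p, S, lex, hier).nvaf:
                assert phenotype_patient(p, K, lex, hier).nvaf


class TestSemisupervised:
    def oracle(self, gold):
        nvaf = dict(zip(gold["patient_id"], gold["nvaf"]))
        return lambda p: bool(nvaf[p.patient_id])

    def test_complete_lexicon_converges_first_iteration(self, small_cohort,
                                                        lex, hier):
        patients, gold = small_cohort
        train = [p for p in patients if apply_inclusion(p)][:150]
        out_lex, labels, log, warn = semisupervised_iterate(
            train, lex, hier, self.oracle(gold), goal_sensitivity=0.90,
            max_iters=3)
        assert len(log) == 1 and not warn
        assert log[0].synonyms_added == 0
        assert len(out_lex) == len(lex)

    def test_missing_variant_recovered_and_sensitivity_rises(self, lex, hier,
                                                             small_cohort):
        patients, gold = small_cohort
        train = [p for p in patients if apply_inclusion(p)][:200]
        crippled = Lexicon([e for e in lex.entries
                            if e.term not in ("afib", "a fib",
                                              "atrial fibrillation")])
        out_lex, labels, log, warn = semisupervised_iterate(
            train, crippled, hier, self.oracle(gold), goal_sensitivity=0.90,
            max_iters=4)
        sens = [r.sensitivity for r in log]
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))
        if len(log) > 1:
            assert sens[-1] > sens[0]
        assert len(out_lex) > len(crippled)

    def test_impossible_goal_sets_warning(self, small_cohort, lex, hier):
        patients, gold = small_cohort
        train = [p for p in patients if apply_inclusion(p)][:50]
        _, _, log, warn = semisupervised_iterate(
            train, Lexicon(), hier, lambda p: True, goal_sensitivity=1.01,
            max_iters=1)
        assert warn and len(log) == 1
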