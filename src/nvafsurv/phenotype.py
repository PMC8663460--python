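"""Cohort cascade: inclusion, AF detection, exclusions, NVAF classification.

Two surveillance modes are compared throughout: STRUCTURED uses coded ICD-9
evidence only; COMBINED additionally uses non-negated SNOMED CT concepts
extracted from the notes, interpreted with subtype closure over the is-a
hierarchy. A concordance-triage rule (agreement of the two coding systems is
accepted, disagreement goes to review) drives the semisupervised loop that
mines missed surface forms into lexicon synonyms.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable

import pandas as pd

from . import conditions as C
from .extract import code_note
from .simulate import Patient
from .terminology import Hierarchy, Lexicon, add_synonyms, codeset_closure


class SurveillanceMode(Enum):
    STRUCTURED = "structured"
    COMBINED = "combined"


class TriageLabel(Enum):
    TRUE_POSITIVE = "true_positive"
    TRUE_NEGATIVE = "true_negative"
    REVIEW = "review"


EXCLUSION_LABELS = (
    "OTHER_ANTITHROMBOTIC", "MECHANICAL_VALVE", "MITRAL_OR_AORTIC_STENOSIS",
    "PREGNANCY", "TRANSIENT_REVERSIBLE_AF", "ENDOCARDITIS",
)

#: Days within which an AF code and a reversible-cause code count as
#: transient AF (window undocumented upstream; declared and configurable).
REVERSIBLE_AF_WINDOW_DAYS = 30


@dataclass
class PhenotypeResult:
    patient_id: str
    mode: SurveillanceMode
    included: bool
    af: bool = False
    vaf: bool = False
    nvaf: bool = False
    exclusions: set[str] = field(default_factory=set)


def apply_inclusion(p: Patient) -> bool:
    """Age 18-90 inclusive, >=1 outpatient visit, >=1 note."""
    if p.age is None:
        raise ValueError(f"patient {p.patient_id} has no age recorded")
    return 18 <= p.age <= 90 and p.outpatient_visits >= 1 and len(p.notes) >= 1


def note_code_set(p: Patient, lex: Lexicon) -> set[tuple[str, str]]:
    """Union of non-negated (system, code) mentions over the patient's notes."""
    out: set[tuple[str, str]] = set()
    for note in p.notes:
        out |= code_note(note, lex)
    return out


def dated_evidence(p: Patient, mode: SurveillanceMode, lex: Lexicon,
                   note_codes: set[tuple[str, str]] | None = None,
                   ) -> list[tuple[str, str, str]]:
    """(date, system, code) evidence items for the mode."""
    ev = list(p.structured_codes)
    if mode is SurveillanceMode.COMBINED:
        if note_codes is None:
            for note in p.notes:
                ev.extend((note.date, s, c) for (s, c) in code_note(note, lex))
        else:
            date = p.notes[0].date if p.notes else ""
            ev.extend((date, s, c) for (s, c) in note_codes)
    return ev


def _codes_by_system(evidence: Iterable[tuple[str, str, str]]
                     ) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {"ICD9": set(), "SCT": set()}
    for _, system, code in evidence:
        out.setdefault(system, set()).add(code)
    return out


def _has_condition(codes: dict[str, set[str]], cond_names: Iterable[str],
                   h: Hierarchy | None,
                   code_maps: dict[str, dict[str, set[str]]]) -> bool:
    for name in cond_names:
        cmap = code_maps[name]
        if codes["ICD9"] & cmap["ICD9"]:
            return True
        if codes["SCT"] & codeset_closure(cmap["SCT"], h):
            return True
    return False


def detect_af(p: Patient, mode: SurveillanceMode, lex: Lexicon,
              h: Hierarchy | None,
              note_codes: set[tuple[str, str]] | None = None) -> bool:
    """AF/flutter by ICD-9 427.31/427.32; COMBINED adds SNOMED CT codes
    49436004/5370000 with all subtypes from non-negated note mentions."""
    structured = {c for (_, s, c) in p.structured_codes if s == "ICD9"}
    if structured & set(C.AF_ICD9):
        return True
    if mode is SurveillanceMode.COMBINED:
        if note_codes is None:
            note_codes = note_code_set(p, lex)
        sct = {c for (s, c) in note_codes if s == "SCT"}
        if sct & codeset_closure(C.AF_SCT_ROOTS, h):
            return True
    return False


def apply_exclusions(p: Patient, mode: SurveillanceMode, lex: Lexicon,
                     h: Hierarchy | None,
                     code_maps: dict[str, dict[str, set[str]]] | None = None,
                     note_codes: set[tuple[str, str]] | None = None,
                     reversible_window_days: int = REVERSIBLE_AF_WINDOW_DAYS,
                     ) -> set[str]:
    """Subset of the six exclusion labels supported by the mode's evidence."""
    code_maps = code_maps or C.default_code_maps()
    ev = dated_evidence(p, mode, lex, note_codes)
    codes = _codes_by_system(ev)
    out: set[str] = set()
    if any(cls == "OTHER_ANTITHROMBOTIC" for (_, _, cls) in p.medications):
        out.add("OTHER_ANTITHROMBOTIC")
    if _has_condition(codes, ["mechanical_valve"], h, code_maps):
        out.add("MECHANICAL_VALVE")
    if _has_condition(codes, ["mitral_stenosis", "aortic_stenosis"], h,
                      code_maps):
        out.add("MITRAL_OR_AORTIC_STENOSIS")
    if _has_condition(codes, ["pregnancy"], h, code_maps):
        out.add("PREGNANCY")
    if _has_condition(codes, ["endocarditis"], h, code_maps):
        out.add("ENDOCARDITIS")
    # transient AF: AF code co-occurring with a reversible cause within window
    af_dates = _dates_for(ev, set(C.AF_ICD9),
                          codeset_closure(C.AF_SCT_ROOTS, h))
    rev_map = code_maps["reversible_cause"]
    rev_dates = _dates_for(ev, rev_map["ICD9"],
                           codeset_closure(rev_map["SCT"], h))
    if any(abs((a - r).days) <= reversible_window_days
           for a in af_dates for r in rev_dates):
        out.add("TRANSIENT_REVERSIBLE_AF")
    return out


def _dates_for(evidence: list[tuple[str, str, str]], icd9: set[str],
               sct_closed: set[str]) -> list[dt.date]:
    dates = []
    for date, system, code in evidence:
        if (system == "ICD9" and code in icd9) or \
           (system == "SCT" and code in sct_closed):
            try:
                dates.append(dt.date.fromisoformat(date))
            except (ValueError, TypeError):
                continue
    return dates


def detect_vhd(p: Patient, mode: SurveillanceMode, lex: Lexicon,
               h: Hierarchy | None,
               code_maps: dict[str, dict[str, set[str]]] | None = None,
               note_codes: set[tuple[str, str]] | None = None) -> bool:
    code_maps = code_maps or C.default_code_maps()
    codes = _codes_by_system(dated_evidence(p, mode, lex, note_codes))
    return _has_condition(
        codes, ["mitral_stenosis", "aortic_stenosis", "mechanical_valve"],
        h, code_maps)


def classify_nvaf(patient_id: str, mode: SurveillanceMode, included: bool,
                  af: bool, vaf_evidence: bool,
                  exclusions: set[str]) -> PhenotypeResult:
    """NVAF = AF without valvular-disease evidence and with no exclusion."""
    if not included:
        return PhenotypeResult(patient_id, mode, included=False)
    nvaf = af and not vaf_evidence and not exclusions
    return PhenotypeResult(patient_id, mode, included=True, af=af,
                           vaf=af and vaf_evidence, nvaf=nvaf,
                           exclusions=set(exclusions))


def phenotype_patient(p: Patient, mode: SurveillanceMode, lex: Lexicon,
                      h: Hierarchy | None,
                      code_maps: dict[str, dict[str, set[str]]] | None = None,
                      note_codes: set[tuple[str, str]] | None = None,
                      ) -> PhenotypeResult:
    included = apply_inclusion(p)
    if not included:
        return PhenotypeResult(p.patient_id, mode, included=False)
    if note_codes is None and mode is SurveillanceMode.COMBINED:
        note_codes = note_code_set(p, lex)
    af = detect_af(p, mode, lex, h, note_codes)
    vaf_ev = detect_vhd(p, mode, lex, h, code_maps, note_codes)
    excl = apply_exclusions(p, mode, lex, h, code_maps, note_codes)
    return classify_nvaf(p.patient_id, mode, included, af, vaf_ev, excl)


def phenotype_cohort(patients: list[Patient], lex: Lexicon,
                     h: Hierarchy | None,
                     code_maps: dict[str, dict[str, set[str]]] | None = None,
                     ) -> pd.DataFrame:
    """Both modes for every patient; one row per (patient, mode)."""
    rows = []
    for p in patients:
        note_codes = note_code_set(p, lex) if apply_inclusion(p) else set()
        for mode in SurveillanceMode:
            r = phenotype_patient(p, mode, lex, h, code_maps, note_codes)
            rows.append({
                "patient_id": r.patient_id, "mode": mode.value,
                "included": r.included, "af": r.af, "vaf": r.vaf,
                "nvaf": r.nvaf,
                "exclusions": ";".join(sorted(r.exclusions)),
            })
    return pd.DataFrame(rows, columns=["patient_id", "mode", "included",
                                       "af", "vaf", "nvaf", "exclusions"])


def concordance_triage(structured_nvaf: bool,
                       combined_nvaf: bool) -> TriageLabel:
    """Agreement of the two coding systems is accepted; disagreement reviews."""
    if structured_nvaf and combined_nvaf:
        return TriageLabel.TRUE_POSITIVE
    if not structured_nvaf and not combined_nvaf:
        return TriageLabel.TRUE_NEGATIVE
    return TriageLabel.REVIEW


@dataclass
class IterationRecord:
    iteration: int
    sensitivity: float
    ppv: float
    synonyms_added: int


def semisupervised_iterate(
    train: list[Patient], lex: Lexicon, h: Hierarchy | None,
    review_oracle: Callable[[Patient], bool],
    candidate_vocab: Iterable[tuple[str, str, str]] | None = None,
    goal_sensitivity: float = 0.95,
    max_iters: int = 5,
    code_maps: dict[str, dict[str, set[str]]] | None = None,
) -> tuple[Lexicon, pd.DataFrame, list[IterationRecord], bool]:
    """Concordance-triage / adjudication / synonym-mining loop.

    Each round compares the two coding systems patient by patient: the
    structured (ICD-9) NVAF call against the note-derived (SNOMED CT) call
    made from the notes alone. Agreement is accepted as a true positive or
    true negative; disagreement goes to the review oracle. Notes of
    adjudicated positives the note-derived system missed are mined for
    candidate surface forms (default: the condition registry's variant
    vocabulary) not yet in the lexicon, which are added as synonyms. Stops
    once the note-derived system's sensitivity against the adjudicated
    labels reaches ``goal_sensitivity``. Returns (lexicon, label table,
    per-iteration log, warning flag); the warning flag is set when the goal
    was not reached by ``max_iters``.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    if candidate_vocab is None:
        candidate_vocab = C.default_lexicon_triples()
    candidate_vocab = list(candidate_vocab)
    log: list[IterationRecord] = []
    labels_df = pd.DataFrame()
    warning = True
    for it in range(1, max_iters + 1):
        rows = []
        fn_patients: list[Patient] = []
        for p in train:
            s = phenotype_patient(p, SurveillanceMode.STRUCTURED, lex, h,
                                  code_maps).nvaf
            notes_only = dataclasses.replace(p, structured_codes=[])
            nlp = phenotype_patient(notes_only, SurveillanceMode.COMBINED,
                                    lex, h, code_maps).nvaf
            triage = concordance_triage(s, nlp)
            if triage is TriageLabel.TRUE_POSITIVE:
                label = True
            elif triage is TriageLabel.TRUE_NEGATIVE:
                label = False
            else:
                label = bool(review_oracle(p))
            if label and not nlp:
                fn_patients.append(p)
            rows.append({"patient_id": p.patient_id, "structured": s,
                         "nlp": nlp, "combined": s or nlp,
                         "triage": triage.value, "label": label})
        labels_df = pd.DataFrame(rows)
        pos = labels_df["label"].sum()
        tp = int((labels_df["label"] & labels_df["nlp"]).sum())
        called = int(labels_df["nlp"].sum())
        sens = tp / pos if pos else 1.0
        ppv = tp / called if called else 1.0

        added: list[tuple[str, str, str]] = []
        if sens < goal_sensitivity:
            texts = [" ".join(n.text.casefold() for n in p.notes)
                     for p in fn_patients]
            for term, code, system in candidate_vocab:
                if (term, code, system) in lex:
                    continue
                needle = term.casefold()
                if any(needle in t for t in texts):
                    added.append((term, code, system))
            if added:
                lex = add_synonyms(lex, added)
        log.append(IterationRecord(it, float(sens), float(ppv), len(added)))
        if sens >= goal_sensitivity:
            warning = False
            break
        if not added:
            break  # nothing more to mine; further rounds are identical
    return lex, labels_df, log, warning
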