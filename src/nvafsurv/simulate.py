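"""Synthetic EHR cohort with known ground truth.

The generator emulates the data situation of an outpatient faculty-practice
EHR: every patient has a true-condition layer (the gold standard), structured
ICD-9 codes that capture each true condition only with a configurable
per-condition sensitivity (atrial fibrillation defaults to 0.54), and
clinical notes that mention true conditions nearly completely (default 0.99)
through randomly chosen synonym/abbreviation variants, plus templated
negated distractor sentences about conditions the patient does *not* have.
Valvular-AF, exclusion, and contraindication subpopulations feed the
downstream phenotyping cascade.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import conditions as C

OAC_DRUGS = ("warfarin", "apixaban", "rivaroxaban", "dabigatran")

_INDEX_DATE = dt.date(2014, 6, 30)


@dataclass(frozen=True)
class ClinicalNote:
    patient_id: str
    date: str  # ISO-8601
    text: str


@dataclass
class Patient:
    patient_id: str
    sex: str                      # "F" / "M"
    age: int                      # years at index
    race: str                     # cosmetic
    true_conditions: set[str] = field(default_factory=set)
    structured_codes: list[tuple[str, str, str]] = field(default_factory=list)
    # (date, system, code)
    medications: list[tuple[str, str, str]] = field(default_factory=list)
    # (date, drug, class)
    labs: list[tuple[str, str, float]] = field(default_factory=list)
    # (date, name, value)
    notes: list[ClinicalNote] = field(default_factory=list)
    outpatient_visits: int = 0


def _default_structured_sensitivity() -> dict[str, float]:
    sens = {name: 0.70 for name in C.ALL_CONDITIONS}
    sens["af"] = 0.54
    # cascade-defining conditions are coded reliably so that exclusions fire
    # under the structured mode too
    for name in (*C.VHD_CONDITIONS, *C.EXCLUSION_CONDITIONS,
                 *C.CONTRAINDICATION_CONDITIONS):
        sens[name] = 0.90
    return sens


def _default_note_sensitivity() -> dict[str, float]:
    return {name: 0.99 for name in C.ALL_CONDITIONS}


def _default_component_prevalences() -> dict[str, float]:
    return {
        "chf": 0.15, "hypertension": 0.55, "diabetes": 0.25,
        "stroke_tia": 0.12, "vascular_disease": 0.20,
        "renal_abnormal": 0.10, "liver_abnormal": 0.05,
        "bleeding_history": 0.08, "labile_inr": 0.06,
        "drug_use": 0.04, "alcohol_use": 0.12,
    }


@dataclass
class SimConfig:
    n_patients: int = 2000
    seed: int = 7
    age_range: tuple[int, int] = (18, 90)
    female_fraction: float = 0.5
    nvaf_prevalence: float = 0.10
    vaf_fraction_of_af: float = 0.30
    component_prevalences: dict[str, float] = field(
        default_factory=_default_component_prevalences)
    structured_sensitivity: dict[str, float] = field(
        default_factory=_default_structured_sensitivity)
    structured_ppv_noise: float = 0.005
    note_sensitivity: dict[str, float] = field(
        default_factory=_default_note_sensitivity)
    negated_distractor_rate: float = 0.3
    contraindication_rate: float = 0.05
    other_exclusion_rate: float = 0.01
    oac_treated_fraction: float = 0.393
    no_note_rate: float = 0.02
    no_visit_rate: float = 0.02
    simulate_inr_series: bool = False  # labile INR stays a boolean condition

    def validate(self) -> None:
        probs = {
            "female_fraction": self.female_fraction,
            "nvaf_prevalence": self.nvaf_prevalence,
            "vaf_fraction_of_af": self.vaf_fraction_of_af,
            "structured_ppv_noise": self.structured_ppv_noise,
            "negated_distractor_rate": self.negated_distractor_rate,
            "contraindication_rate": self.contraindication_rate,
            "other_exclusion_rate": self.other_exclusion_rate,
            "oac_treated_fraction": self.oac_treated_fraction,
            "no_note_rate": self.no_note_rate,
            "no_visit_rate": self.no_visit_rate,
            **{f"component_prevalences[{k}]": v
               for k, v in self.component_prevalences.items()},
            **{f"structured_sensitivity[{k}]": v
               for k, v in self.structured_sensitivity.items()},
            **{f"note_sensitivity[{k}]": v
               for k, v in self.note_sensitivity.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} = {p} outside [0, 1]")
        lo, hi = self.age_range
        if not (18 <= lo <= hi <= 90):
            raise ValueError(f"age_range {self.age_range} outside [18, 90]")
        if self.vaf_fraction_of_af < 1.0:
            af_prev = self.nvaf_prevalence / (1.0 - self.vaf_fraction_of_af)
            if af_prev > 1.0:
                raise ValueError("implied AF prevalence exceeds 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


def _rand_date(rng: np.random.Generator,
               start: dt.date = dt.date(2010, 1, 1),
               end: dt.date = dt.date(2015, 9, 21)) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def render_note(patient_id: str, mentioned: Iterable[str],
                absent: Iterable[str], date: str,
                templates: dict[str, tuple[str, ...]],
                rng: np.random.Generator,
                negated_distractor_rate: float = 0.0) -> ClinicalNote:
    """One affirmative sentence per mentioned condition, plus distractors.

    With probability ``negated_distractor_rate`` a "No <variant>." sentence
    is appended for a condition the patient does not have.
    """
    sentences: list[str] = []
    for cond in mentioned:
        if cond not in templates:
            raise KeyError(f"no note template for condition {cond!r}")
        variant = templates[cond][int(rng.integers(len(templates[cond])))]
        sentences.append(f"Patient has {variant}.")
    absent = list(absent)
    if absent and rng.random() < negated_distractor_rate:
        cond = absent[int(rng.integers(len(absent)))]
        if cond not in templates:
            raise KeyError(f"no note template for condition {cond!r}")
        variant = templates[cond][int(rng.integers(len(templates[cond])))]
        sentences.append(f"No {variant}.")
    return ClinicalNote(patient_id, date, " ".join(sentences))


def generate_cohort(cfg: SimConfig) -> tuple[list[Patient], pd.DataFrame]:
    """Generate patients plus the per-patient gold-truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    templates = C.note_templates()
    patients: list[Patient] = []
    gold_rows: list[dict] = []

    af_prev = (cfg.nvaf_prevalence / (1.0 - cfg.vaf_fraction_of_af)
               if cfg.vaf_fraction_of_af < 1.0 else cfg.nvaf_prevalence)

    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        sex = "F" if rng.random() < cfg.female_fraction else "M"
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        race = ("White", "Black", "Asian", "Other")[
            int(rng.choice(4, p=[0.75, 0.12, 0.05, 0.08]))]

        true: set[str] = set()
        has_af = rng.random() < af_prev
        is_vaf = has_af and rng.random() < cfg.vaf_fraction_of_af
        if has_af:
            true.add("af")
        if is_vaf:
            vhd = list(C.VHD_CONDITIONS)[int(rng.integers(len(C.VHD_CONDITIONS)))]
            true.add(vhd)
        for cond, prev in cfg.component_prevalences.items():
            if rng.random() < prev:
                true.add(cond)
        contraindicated = rng.random() < cfg.contraindication_rate
        if contraindicated:
            ctr = list(C.CONTRAINDICATION_CONDITIONS)[
                int(rng.integers(len(C.CONTRAINDICATION_CONDITIONS)))]
            true.add(ctr)
        other_exclusions: set[str] = set()
        if sex == "F" and age < 45 and rng.random() < cfg.other_exclusion_rate:
            other_exclusions.add("pregnancy")
        if rng.random() < cfg.other_exclusion_rate:
            other_exclusions.add("endocarditis")
        if has_af and rng.random() < cfg.other_exclusion_rate:
            other_exclusions.add("reversible_cause")  # transient AF trigger
        true |= other_exclusions

        # --- structured codes: imperfect capture of the truth --------------
        codes: list[tuple[str, str, str]] = []
        af_date = _rand_date(rng)
        for cond in sorted(true):
            sens = cfg.structured_sensitivity.get(cond, 0.70)
            if rng.random() < sens:
                icd = C.ALL_CONDITIONS[cond].icd9
                code = icd[int(rng.integers(len(icd)))]
                date = af_date if cond == "af" else _rand_date(rng)
                if cond == "reversible_cause":
                    # transient AF: reversible cause coded close to AF
                    date = af_date + dt.timedelta(days=int(rng.integers(0, 15)))
                codes.append((date.isoformat(), "ICD9", code))
        for cond in sorted(set(C.ALL_CONDITIONS) - true):
            if rng.random() < cfg.structured_ppv_noise:
                icd = C.ALL_CONDITIONS[cond].icd9
                codes.append((_rand_date(rng).isoformat(), "ICD9",
                              icd[int(rng.integers(len(icd)))]))

        # --- note mentions: near-complete capture --------------------------
        mentioned = [cond for cond in sorted(true)
                     if rng.random() < cfg.note_sensitivity.get(cond, 0.99)]
        absent = sorted(set(C.ALL_CONDITIONS) - true)
        note_date = af_date.isoformat() if has_af else _rand_date(rng).isoformat()
        notes: list[ClinicalNote] = []
        if rng.random() >= cfg.no_note_rate:
            notes.append(render_note(pid, mentioned, absent, note_date,
                                     templates, rng,
                                     cfg.negated_distractor_rate))

        visits = 0 if rng.random() < cfg.no_visit_rate else \
            1 + int(rng.poisson(3))

        # --- gold eligibility and treatment --------------------------------
        gold_nvaf = has_af and not is_vaf and not other_exclusions
        meds: list[tuple[str, str, str]] = []
        age_pts = 2 if age >= 75 else (1 if age >= 65 else 0)
        gold_chads = (("chf" in true) + ("hypertension" in true)
                      + ("diabetes" in true) + 2 * ("stroke_tia" in true)
                      + ("vascular_disease" in true) + (sex == "F") + age_pts)
        gold_has_bled = (("hypertension" in true) + ("renal_abnormal" in true)
                         + ("liver_abnormal" in true) + ("stroke_tia" in true)
                         + ("bleeding_history" in true)
                         + ("labile_inr" in true) + (age > 65)
                         + ("drug_use" in true) + ("alcohol_use" in true))
        eligible = gold_nvaf and gold_chads >= 2 and not contraindicated
        on_oac = eligible and rng.random() < cfg.oac_treated_fraction
        if on_oac:
            drug = OAC_DRUGS[int(rng.integers(len(OAC_DRUGS)))]
            meds.append((_rand_date(rng).isoformat(), drug, "OAC"))
        if not has_af and rng.random() < cfg.other_exclusion_rate:
            meds.append((_rand_date(rng).isoformat(), "clopidogrel",
                         "OTHER_ANTITHROMBOTIC"))
        labs = [(note_date, "INR", round(float(rng.normal(2.5, 0.8)), 2))] \
            if "labile_inr" in true else []

        patients.append(Patient(
            patient_id=pid, sex=sex, age=age, race=race,
            true_conditions=true, structured_codes=codes,
            medications=meds, labs=labs, notes=notes,
            outpatient_visits=visits))
        gold_rows.append({
            "patient_id": pid, "sex": sex, "age": age,
            "af": has_af, "vaf": is_vaf, "nvaf": gold_nvaf,
            **{cond: (cond in true) for cond in sorted(C.RISK_CONDITIONS)},
            "contraindicated": contraindicated,
            "excluded_other": bool(other_exclusions),
            "gold_chads_vasc": gold_chads,
            "gold_has_bled": gold_has_bled,
            "eligible": eligible, "on_oac": on_oac,
            "mentioned_in_note": ";".join(mentioned),
        })

    gold = pd.DataFrame(
        gold_rows if gold_rows else None,
        columns=["patient_id", "sex", "age", "af", "vaf", "nvaf",
                 *sorted(C.RISK_CONDITIONS), "contraindicated",
                 "excluded_other", "gold_chads_vasc", "gold_has_bled",
                 "eligible", "on_oac", "mentioned_in_note"])
    return patients, gold


def write_dataset(patients: list[Patient], gold: pd.DataFrame,
                  out_dir: str | Path) -> dict[str, Path]:
    """Emit patients/codes/meds/labs CSVs, notes JSONL, and gold CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in (
        ("patients", "patients.csv"), ("codes", "codes.csv"),
        ("meds", "meds.csv"), ("labs", "labs.csv"),
        ("notes", "notes.jsonl"), ("gold", "gold.csv"))}
    try:
        pd.DataFrame(
            [(p.patient_id, p.sex, p.age, p.race, p.outpatient_visits)
             for p in patients],
            columns=["patient_id", "sex", "age", "race", "outpatient_visits"],
        ).to_csv(paths["patients"], index=False)
        pd.DataFrame(
            [(p.patient_id, d, s, c) for p in patients
             for (d, s, c) in p.structured_codes],
            columns=["patient_id", "date", "system", "code"],
        ).to_csv(paths["codes"], index=False)
        pd.DataFrame(
            [(p.patient_id, d, drug, cls) for p in patients
             for (d, drug, cls) in p.medications],
            columns=["patient_id", "date", "drug", "class"],
        ).to_csv(paths["meds"], index=False)
        pd.DataFrame(
            [(p.patient_id, d, name, val) for p in patients
             for (d, name, val) in p.labs],
            columns=["patient_id", "date", "name", "value"],
        ).to_csv(paths["labs"], index=False)
        with open(paths["notes"], "w", encoding="utf-8") as fh:
            for p in patients:
                for note in p.notes:
                    fh.write(json.dumps(
                        {"patient_id": note.patient_id, "date": note.date,
                         "text": note.text}) + "\n")
        gold.to_csv(paths["gold"], index=False)
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return paths


def read_dataset(in_dir: str | Path) -> tuple[list[Patient], pd.DataFrame]:
    """Reconstruct patients and gold table from a ``write_dataset`` directory."""
    d = Path(in_dir)
    pts = pd.read_csv(d / "patients.csv", dtype={"patient_id": str})
    codes = pd.read_csv(d / "codes.csv",
                        dtype={"patient_id": str, "code": str})
    meds = pd.read_csv(d / "meds.csv", dtype={"patient_id": str})
    labs = pd.read_csv(d / "labs.csv", dtype={"patient_id": str})
    notes: dict[str, list[ClinicalNote]] = {}
    notes_path = d / "notes.jsonl"
    if notes_path.exists():
        with open(notes_path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    obj = json.loads(line)
                    notes.setdefault(obj["patient_id"], []).append(
                        ClinicalNote(obj["patient_id"], obj["date"],
                                     obj["text"]))
    gold = pd.read_csv(d / "gold.csv", dtype={"patient_id": str})
    by_pid = {}
    for row in pts.itertuples(index=False):
        by_pid[row.patient_id] = Patient(
            patient_id=row.patient_id, sex=row.sex, age=int(row.age),
            race=row.race, outpatient_visits=int(row.outpatient_visits),
            notes=notes.get(row.patient_id, []))
    for row in codes.itertuples(index=False):
        by_pid[row.patient_id].structured_codes.append(
            (row.date, row.system, row.code))
    for row in meds.itertuples(index=False):
        by_pid[row[0]].medications.append((row[1], row[2], row[3]))
    for row in labs.itertuples(index=False):
        by_pid[row.patient_id].labs.append((row.date, row.name, row.value))
    return list(by_pid.values()), gold
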