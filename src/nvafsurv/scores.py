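"""CHA2DS2-VASc and HAS-BLED scoring and the treatment recommendation rule.

Component flags are derived from the surveillance mode's evidence set
(structured codes alone, or structured plus non-negated note concepts);
weights follow the published score definitions and live in module-level
tables so a deployment can audit or override them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from . import conditions as C
from .phenotype import SurveillanceMode, _codes_by_system, dated_evidence
from .simulate import Patient
from .terminology import Hierarchy, Lexicon, codeset_closure

#: Published CHA2DS2-VASc weights (max 9).
CHADS_VASC_WEIGHTS: dict[str, int] = {
    "chf": 1, "hypertension": 1, "age_ge_75": 2, "diabetes": 1,
    "stroke_tia": 2, "vascular_disease": 1, "age_65_74": 1, "female": 1,
}

#: Published HAS-BLED weights: one point per component, renal/liver and
#: drug/alcohol scored separately (max 9).
HAS_BLED_WEIGHTS: dict[str, int] = {
    "htn_uncontrolled": 1, "renal_abnormal": 1, "liver_abnormal": 1,
    "stroke_history": 1, "bleeding_history": 1, "labile_inr": 1,
    "elderly_gt_65": 1, "drug_use": 1, "alcohol_use": 1,
}

#: Guideline convention used here: female sex scores 1 point and the
#: treatment threshold is >=2 regardless of sex. The later sex-specific
#: threshold update is available as a toggle on ``recommend``.
CHADS_VASC_TREAT_THRESHOLD = 2
HAS_BLED_HIGH_RISK_THRESHOLD = 3


@dataclass
class RiskComponents:
    # CHA2DS2-VASc
    chf: bool = False
    hypertension: bool = False
    age_ge_75: bool = False
    diabetes: bool = False
    stroke_tia: bool = False
    vascular_disease: bool = False
    age_65_74: bool = False
    female: bool = False
    # HAS-BLED
    htn_uncontrolled: bool = False
    renal_abnormal: bool = False
    liver_abnormal: bool = False
    stroke_history: bool = False
    bleeding_history: bool = False
    labile_inr: bool = False
    elderly_gt_65: bool = False
    drug_use: bool = False
    alcohol_use: bool = False

    def __post_init__(self) -> None:
        if self.age_ge_75 and self.age_65_74:
            raise ValueError("age bands >=75 and 65-74 are mutually exclusive")


@dataclass
class RiskProfile:
    patient_id: str
    mode: SurveillanceMode
    components: RiskComponents
    chads_vasc: int
    has_bled: int
    contraindicated: bool = False
    on_oac: bool = False


class Recommendation(Enum):
    TREAT = "treat"
    NO_TREAT = "no_treat"
    CONTRAINDICATED = "contraindicated"


def chads_vasc_score(c: RiskComponents) -> int:
    if c.age_ge_75 and c.age_65_74:
        raise ValueError("age bands >=75 and 65-74 are mutually exclusive")
    return sum(w for name, w in CHADS_VASC_WEIGHTS.items()
               if getattr(c, name))


def has_bled_score(c: RiskComponents) -> int:
    return sum(w for name, w in HAS_BLED_WEIGHTS.items() if getattr(c, name))


def extract_components(p: Patient, mode: SurveillanceMode, lex: Lexicon,
                       h: Hierarchy | None,
                       code_maps: dict[str, dict[str, set[str]]] | None = None,
                       note_codes: set[tuple[str, str]] | None = None,
                       ) -> RiskComponents:
    """Component booleans from the mode's evidence set plus demographics.

    The HAS-BLED hypertension component defaults to the same hypertension
    code list (its "uncontrolled" qualifier has no agreed coding and can be
    overridden through ``code_maps``); stroke history shares the stroke/TIA
    list; elderly is age > 65 at index.
    """
    if p.age is None or p.sex is None:
        raise ValueError(f"patient {p.patient_id} missing demographics")
    code_maps = code_maps or C.default_code_maps()
    codes = _codes_by_system(dated_evidence(p, mode, lex, note_codes))

    def has(cond: str) -> bool:
        cmap = code_maps[cond]
        return bool(codes["ICD9"] & cmap["ICD9"]) or \
            bool(codes["SCT"] & codeset_closure(cmap["SCT"], h))

    return RiskComponents(
        chf=has("chf"),
        hypertension=has("hypertension"),
        age_ge_75=p.age >= 75,
        diabetes=has("diabetes"),
        stroke_tia=has("stroke_tia"),
        vascular_disease=has("vascular_disease"),
        age_65_74=65 <= p.age < 75,
        female=p.sex == "F",
        htn_uncontrolled=has("hypertension"),
        renal_abnormal=has("renal_abnormal"),
        liver_abnormal=has("liver_abnormal"),
        stroke_history=has("stroke_tia"),
        bleeding_history=has("bleeding_history"),
        labile_inr=has("labile_inr"),
        elderly_gt_65=p.age > 65,
        drug_use=has("drug_use"),
        alcohol_use=has("alcohol_use"),
    )


def is_contraindicated(p: Patient, mode: SurveillanceMode, lex: Lexicon,
                       h: Hierarchy | None,
                       code_maps: dict[str, dict[str, set[str]]] | None = None,
                       note_codes: set[tuple[str, str]] | None = None) -> bool:
    code_maps = code_maps or C.default_code_maps()
    codes = _codes_by_system(dated_evidence(p, mode, lex, note_codes))
    for cond in C.CONTRAINDICATION_CONDITIONS:
        cmap = code_maps[cond]
        if codes["ICD9"] & cmap["ICD9"] or \
                codes["SCT"] & codeset_closure(cmap["SCT"], h):
            return True
    return False


def risk_profile(p: Patient, mode: SurveillanceMode, lex: Lexicon,
                 h: Hierarchy | None,
                 code_maps: dict[str, dict[str, set[str]]] | None = None,
                 note_codes: set[tuple[str, str]] | None = None) -> RiskProfile:
    comp = extract_components(p, mode, lex, h, code_maps, note_codes)
    return RiskProfile(
        patient_id=p.patient_id, mode=mode, components=comp,
        chads_vasc=chads_vasc_score(comp), has_bled=has_bled_score(comp),
        contraindicated=is_contraindicated(p, mode, lex, h, code_maps,
                                           note_codes),
        on_oac=any(cls == "OAC" for (_, _, cls) in p.medications))


def recommend(profile: RiskProfile,
              female_threshold_adjust: bool = False
              ) -> tuple[Recommendation, bool]:
    """(recommendation, high_bleed_risk).

    TREAT when CHA2DS2-VASc >= 2 and no contraindication; a contraindication
    overrides. High bleed risk (HAS-BLED >= 3) is reported alongside and
    never blocks treatment by itself. ``female_threshold_adjust`` raises the
    threshold to >=3 for women (the later guideline update), default off.
    """
    threshold = CHADS_VASC_TREAT_THRESHOLD
    if female_threshold_adjust and profile.components.female:
        threshold += 1
    high_bleed = profile.has_bled >= HAS_BLED_HIGH_RISK_THRESHOLD
    if profile.contraindicated:
        return Recommendation.CONTRAINDICATED, high_bleed
    if profile.chads_vasc >= threshold:
        return Recommendation.TREAT, high_bleed
    return Recommendation.NO_TREAT, high_bleed
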