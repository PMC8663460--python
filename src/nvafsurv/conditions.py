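"""Registry of clinical conditions used across the surveillance pipeline.

Each condition carries its ICD-9 codes (the structured-data vocabulary), a
SNOMED CT root code (the note-derived vocabulary; matching applies subtype
closure over the shipped hierarchy), and the surface variants that the
synthetic note generator and the semisupervised synonym miner draw from.

The code lists are a reconstructed mini-terminology, not a licensed SNOMED CT
or ICD-9-CM release; every list is plain data and user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Condition:
    name: str
    icd9: tuple[str, ...]
    sct: str
    variants: tuple[str, ...]


# --- atrial fibrillation / flutter ------------------------------------------
AF_ICD9 = ("427.31", "427.32")
AF_SCT_ROOTS = ("49436004", "5370000")  # atrial fibrillation, atrial flutter

AF = Condition(
    "af",
    AF_ICD9,
    "49436004",
    (
        "atrial fibrillation",
        "afib",
        "a fib",
        "paroxysmal atrial fibrillation",
        "chronic atrial fibrillation",
        "atrial flutter",
    ),
)

# --- stroke-risk and bleed-risk components ----------------------------------
RISK_CONDITIONS: dict[str, Condition] = {
    c.name: c
    for c in (
        Condition("chf", ("428.0",), "42343007",
                  ("congestive heart failure", "chf", "heart failure")),
        Condition("hypertension", ("401.9",), "38341003",
                  ("hypertension", "htn", "high blood pressure")),
        Condition("diabetes", ("250.00",), "73211009",
                  ("diabetes mellitus", "diabetes", "dm")),
        Condition("stroke_tia", ("434.91", "435.9"), "230690007",
                  ("stroke", "cerebrovascular accident", "cva",
                   "transient ischemic attack", "tia")),
        Condition("vascular_disease", ("414.01", "443.9"), "53741008",
                  ("coronary artery disease", "cad",
                   "peripheral vascular disease", "pvd")),
        Condition("renal_abnormal", ("585.9",), "709044004",
                  ("chronic kidney disease", "ckd", "renal insufficiency")),
        Condition("liver_abnormal", ("571.9",), "235856003",
                  ("cirrhosis", "chronic liver disease")),
        Condition("bleeding_history", ("459.0",), "131148009",
                  ("history of bleeding", "gi bleed", "bleeding tendency")),
        Condition("labile_inr", ("790.92",), "166636006",
                  ("labile inr", "unstable inr")),
        Condition("drug_use", ("304.90",), "66214007",
                  ("drug dependence", "substance abuse")),
        Condition("alcohol_use", ("305.00",), "7200002",
                  ("alcohol abuse", "alcoholism", "etoh abuse")),
    )
}

# --- valvular heart disease (makes AF valvular) ------------------------------
VHD_SCT_ROOT = "368009"  # heart valve disorder
VHD_CONDITIONS: dict[str, Condition] = {
    c.name: c
    for c in (
        Condition("mitral_stenosis", ("394.0",), "79619009",
                  ("mitral stenosis", "ms of the mitral valve")),
        Condition("aortic_stenosis", ("395.0",), "60573004",
                  ("aortic stenosis", "severe aortic stenosis")),
        Condition("mechanical_valve", ("V43.3",), "426263006",
                  ("mechanical prosthetic valve", "mechanical heart valve")),
    )
}

# --- exclusion-cascade conditions beyond VHD ---------------------------------
EXCLUSION_CONDITIONS: dict[str, Condition] = {
    c.name: c
    for c in (
        Condition("pregnancy", ("V22.2",), "77386006",
                  ("pregnant", "pregnancy")),
        Condition("endocarditis", ("421.0",), "56819008",
                  ("infective endocarditis", "endocarditis")),
        Condition("reversible_cause", ("242.90",), "34486009",
                  ("hyperthyroidism", "thyrotoxicosis")),
    )
}

# --- OAC contraindications (reconstructed default list) ----------------------
CONTRAINDICATION_CONDITIONS: dict[str, Condition] = {
    c.name: c
    for c in (
        Condition("active_bleeding", ("578.9",), "74474003",
                  ("active gastrointestinal bleeding", "active major bleeding")),
        Condition("thrombocytopenia", ("287.5",), "302215000",
                  ("severe thrombocytopenia", "thrombocytopenia")),
        Condition("prior_ich", ("431",), "274100004",
                  ("intracranial hemorrhage", "prior intracranial hemorrhage")),
    )
}

ALL_CONDITIONS: dict[str, Condition] = {
    AF.name: AF,
    **RISK_CONDITIONS,
    **VHD_CONDITIONS,
    **EXCLUSION_CONDITIONS,
    **CONTRAINDICATION_CONDITIONS,
}

#: SNOMED CT is-a edges (child, parent) for the mini-hierarchy. AF subtypes
#: collapse onto the two AF roots; valve lesions onto the VHD root.
HIERARCHY_EDGES: tuple[tuple[str, str], ...] = (
    ("282825002", "49436004"),   # paroxysmal AF
    ("426749004", "49436004"),   # chronic AF
    ("440059007", "49436004"),   # persistent AF
    ("312442005", "5370000"),    # typical atrial flutter
    ("79619009", VHD_SCT_ROOT),
    ("60573004", VHD_SCT_ROOT),
    ("426263006", VHD_SCT_ROOT),
)

#: Subtype-specific lexicon targets: these surface forms resolve to AF
#: subtype codes, exercising subtype closure at query time.
SUBTYPE_LEXICON: tuple[tuple[str, str], ...] = (
    ("paroxysmal atrial fibrillation", "282825002"),
    ("chronic atrial fibrillation", "426749004"),
)


def default_lexicon_triples() -> list[tuple[str, str, str]]:
    """(term, code, system) triples behind the shipped lexicon fixture:
    every condition variant mapped to its SNOMED CT code, with
    subtype-specific surface forms resolving to subtype codes."""
    sub = dict(SUBTYPE_LEXICON)
    triples: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for name, cond in ALL_CONDITIONS.items():
        for v in cond.variants:
            if v in seen:
                continue
            seen.add(v)
            code = sub.get(v, cond.sct)
            if name == "af" and v == "atrial flutter":
                code = "5370000"
            triples.append((v, code, "SCT"))
    return triples


def default_code_maps() -> dict[str, dict[str, set[str]]]:
    """Condition -> per-system evidence code lists (SCT entries are closure roots)."""
    maps: dict[str, dict[str, set[str]]] = {}
    for name, cond in ALL_CONDITIONS.items():
        maps[name] = {"ICD9": set(cond.icd9), "SCT": {cond.sct}}
    maps["af"]["SCT"] = set(AF_SCT_ROOTS)
    return maps


def note_templates() -> dict[str, tuple[str, ...]]:
    """Affirmative sentence templates per condition (>=2 surface variants each)."""
    return {name: cond.variants for name, cond in ALL_CONDITIONS.items()}
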