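"""nvafsurv: EHR bio-surveillance for nonvalvular atrial fibrillation.

Identify NVAF patients from structured codes alone versus structured plus
note-derived concepts, score stroke (CHA2DS2-VASc) and bleeding (HAS-BLED)
risk under each mode, compare the modes against a gold standard with paired
diagnostic statistics, and project national strokes, deaths, and costs
averted.
"""

from importlib import resources as _resources
from pathlib import Path as _Path

from .terminology import (Lexicon, Hierarchy, load_lexicon, load_hierarchy,
                          add_synonyms, subtype_closure, normalize_term)
from .extract import (segment_sentences, tokenize, match_concepts,
                      detect_negation, extract_mentions, code_note,
                      TokenSpan, CodedMention)
from .simulate import (SimConfig, Patient, ClinicalNote, generate_cohort,
                       render_note, write_dataset, read_dataset)
from .phenotype import (SurveillanceMode, TriageLabel, PhenotypeResult,
                        apply_inclusion, detect_af, apply_exclusions,
                        classify_nvaf, concordance_triage, phenotype_patient,
                        phenotype_cohort, semisupervised_iterate)
from .scores import (RiskComponents, RiskProfile, Recommendation,
                     chads_vasc_score, has_bled_score, extract_components,
                     risk_profile, recommend)
from .stats import (DxMetrics, PairedTestResult, AgreementStats,
                    ConcordanceResult, ConcordanceComparison, f_score,
                    paired_confusion, discordant_counts, mcnemar_test,
                    exact_binomial_test, paired_proportion_test,
                    compare_predictive_values, cohens_kappa,
                    icc_two_way_random, ordinal_concordance,
                    compare_concordance)
from .extrapolate import (ClaimsRates, CostParams, ExtrapolationResult,
                          annual_savings_per_stroke, event_rate,
                          inflation_adjust, project_events, build_table4,
                          load_params)

__version__ = "0.1.0"


def data_path(name: str) -> _Path:
    """Path to a shipped data fixture (lexicon.tsv, hierarchy.tsv, params.yaml)."""
    return _Path(str(_resources.files("nvafsurv").joinpath("data", name)))


def default_lexicon() -> Lexicon:
    return load_lexicon(data_path("lexicon.tsv"))


def default_hierarchy() -> Hierarchy:
    return load_hierarchy(data_path("hierarchy.tsv"))
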