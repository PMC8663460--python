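# Methods

## Problem and pipeline

Nonvalvular atrial fibrillation (NVAF) carries a roughly five-fold stroke
risk that oral anticoagulation (OAC) largely removes, yet coded EHR data
capture the diagnosis for only about half of true cases. The pipeline
quantifies what adding note-derived evidence buys: it phenotypes every
patient twice — from structured codes alone and from structured codes plus
dictionary-extracted SNOMED CT concepts — scores stroke (CHA₂DS₂-VASc) and
bleeding (HAS-BLED) risk under each mode, compares both against a gold
standard with paired diagnostics, and projects the national consequences of
closing the detection gap.

All inputs are synthetic or printed parameters; nothing requires access to
proprietary EHR or claims data.

## Concept extraction

The coder is a deliberately transparent stand-in for a full NLP pipeline:
sentences are split on `.!?`/newline with an abbreviation guard, tokenized
into maximal alphanumeric runs (hyphens internal), and scanned left to
right; at each position the longest lexicon term starting there wins
(consumed tokens are not reused; equal-length candidates resolve to the
lexicographically smallest (system, code) — determinism requires *some*
rule and none is canonical). Inexact matching is normalization only
(case-folding, boundary punctuation stripping, whitespace collapse); an
edit-distance notion would need a threshold with no principled default.
Negation is a minimal NegEx-style rule: a trigger ("no", "denies",
"without", "negative for", "not") within 5 tokens *before* a mention in the
same sentence flags it; negated mentions contribute no evidence. Mentions
never cross sentence boundaries. Hypothetical/family-history attribution,
POS tagging and sense disambiguation are out of scope.

The shipped mini-terminology (57 surface forms, ~30 SNOMED CT codes, 7
is-a edges) is a reconstruction covering AF subtypes, valvular disease,
every score component, exclusions and contraindications; every list is
plain TSV/registry data and user-replaceable. Note-derived codes are always
interpreted through subtype closure (a code plus all transitive is-a
descendants), so a "paroxysmal atrial fibrillation" mention satisfies an AF
query.

## Synthetic cohort

Each patient gets a true-condition layer (the gold standard), then two
imperfect views of it:

* **structured codes**: each true condition yields its ICD-9 code by an
  independent Bernoulli draw — sensitivity 0.54 for AF (the published
  structured-coding capture rate), 0.90 for cascade-defining conditions
  (valve disease, exclusions, contraindications), 0.70 otherwise (no
  per-component rates are published; these are configurable, not asserted
  as study-faithful). Spurious codes arise at 0.005 per absent condition,
  keeping structured PPV near 0.95 at the default prevalence.
* **notes**: one note mentioning each true condition with probability 0.99
  through a random synonym/abbreviation variant, plus a "No <condition>."
  distractor about an absent condition with probability 0.3.

Defaults chosen once: NVAF prevalence 0.10 — an enriched practice-panel
rate so that a few-thousand-patient cohort carries hundreds of cases and
the paired comparisons have resolution; valvular fraction of AF 0.30 (NVAF
is ~70% of AF); component prevalences at typical AF-cohort comorbidity
levels (hypertension 0.55 down to drug use 0.04); OAC treatment among
eligible patients 0.393, the lower bound of the reported 39%–65% range;
2% of patients lack notes or visits to exercise the inclusion step. Labile
INR is a boolean condition, not an INR series (its operationalization is
nowhere stated); race and labs are cosmetic schema fields.

What the generator does **not** emulate: realistic clinical language
(templated sentences only), longitudinal disease progression, correlated
comorbidity structure, coding-practice drift, or inter-note redundancy.
Passing tests therefore demonstrate algorithmic correctness and calibration
under the stated miss model — not performance on real clinical text.

## Cascade and scores

Inclusion: age 18–90, ≥1 outpatient visit, ≥1 note (missing age is an
error, never imputed). AF: ICD-9 427.31/427.32 in either mode; combined
mode adds non-negated note codes in the closure of SNOMED CT
49436004/5370000. Exclusions (mode-dependent evidence): other
antithrombotic therapy (medication class), mechanical valve, mitral/aortic
stenosis, pregnancy, endocarditis, and transient AF operationalized as an
AF code within 30 days of a reversible-cause code (the window is declared
and configurable; no value is published). NVAF = AF ∧ no valvular-disease
evidence ∧ no exclusion.

Score weights live in config tables, not code constants. Female sex scores
1 point and the treatment threshold is ≥2 regardless of sex (the
2014-guideline convention); the later sex-specific threshold is a toggle.
The HAS-BLED hypertension component defaults to the same code list as
CHA₂DS₂-VASc hypertension ("uncontrolled" has no agreed coding), stroke
history shares the stroke/TIA list, elderly is age >65. A contraindication
(default list: active major bleeding, severe thrombocytopenia, prior
intracranial hemorrhage — reconstructed, user-replaceable) overrides TREAT;
HAS-BLED ≥3 is reported alongside and never blocks treatment by itself.

The semisupervised loop triages each training patient by agreement of the
two *coding systems* — the ICD-9 call versus the note-only SNOMED CT call.
Agreement is accepted; disagreement goes to the review oracle (in tests,
the gold table). Notes of adjudicated positives the note-derived call
missed are mined for known surface variants absent from the lexicon, which
are added as synonyms; logged sensitivity is non-decreasing because
synonyms only add matches. Comparing structured against *combined* here
would be vacuous: combined evidence is a superset of structured, so that
contrast can never produce a reviewable false negative.

## Statistics

* **Paired proportions**: McNemar χ² = (b−c)²/(b+c) without continuity
  correction (toggle available); when b+c < 25 the exact binomial sign test
  replaces it — doubled smaller tail at p=½, capped at 1. The cutoff is a
  convention; no value is published.
* **Predictive values**: the Leisenring–Alonzo–Pepe generalized score
  statistic. Each subject contributes one record per test whose result
  selects it in (test-positive records for PPV, test-negative for NPV); the
  working-independence GEE score for the test-indicator covariate is
  evaluated under the pooled null with a subject-clustered empirical
  variance; reference χ²₁. Validated against a within-subject label-swap
  permutation oracle on equal-positivity constructions (where the swap null
  holds); with unequal positivity the permutation tests a stronger
  exchangeability null and is not a valid reference for equal predictive
  values.
* **Agreement**: Cohen's κ closed form with degenerate-marginal flagging
  (p_e → 1); ICC(2,1) from the two-way ANOVA decomposition. Both use
  subject-resampling percentile bootstrap CIs, default 10,000 replicates,
  seedable (pipeline runs use fewer for speed; the replicate count is
  configuration, not inference).
* **Ordinal concordance**: C and Somers' D by rank concordance over
  gold-untied pairs (predictor ties count half; D = 2C − 1 identically). A
  proportional-odds fit is unnecessary for a single monotone predictor —
  the concordance probability is the same. SEs and the paired ΔD Z test use
  delete-one jackknife (deterministic given data); jackknife leave-one-out
  values are computed in O(n) from per-subject pair sums.

Degenerate inputs are flagged, not silently patched: κ with constant
identical raters, ICC with zero between-subject variance, concordance with
all-equal gold, zero discordant pairs.

## National projection

Forward chain from the claims-derived inputs: strokes = needing_treatment ×
0.0444 (rounded half-up), deaths = strokes × 0.0599, savings = strokes ×
$102,680 (12 × the inflation-adjusted $8,556.66 monthly pre/post-stroke
cost difference). Net benefit defaults to the two-term form savings −
therapy cost; induced-bleed cost (rate 0.34%/yr, $23,777.67 per bleed) is
computed and reported separately, with an opt-in flag to subtract it. The
national NVAF populations per method and the national therapy cost are
config inputs: the census-scaling step and the treated-population
denominator behind them are not derivable from the stated rates, so the
pipeline computes forward from the "needing treatment" counts and applies
the printed therapy cost to the combined column (a pmpm × 12 product is the
fallback when the override is unset). Counts round half-up at each stage;
dollar totals are exact products of rounded counts.

## Problem sizes and reproducibility

Default demonstration and test cohorts are 300–2,000 patients with
bootstrap/permutation sizes of 100–10,000 — large enough that the binomial
99% interval around the configured 0.54 capture rate spans only ~±0.09 at
~200 gold cases, and chosen as the package's own demonstration scale.
Every stochastic stage draws from a seeded generator; identical
configuration yields byte-identical dataset files and stage outputs.

## Known limitations

Templated language means extraction is essentially noise-free given the
lexicon; real-text performance is untested by construction. Independence of
per-condition draws understates comorbidity correlation, so score
distributions are narrower than clinical reality. The exclusion and
contraindication code lists are reconstructions. The ICD-9 vocabulary is
frozen; ICD-10 migration is out of scope.
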