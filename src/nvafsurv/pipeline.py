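"""End-to-end orchestration: simulate -> extract -> phenotype -> score ->
compare -> extrapolate, with per-stage CSV outputs, a run log, and report
tables (method accuracy, score-level comparisons, cascade counts and claims
event rates, national projection)."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (default_hierarchy, default_lexicon, data_path, __version__)
from .extract import extract_mentions
from .extrapolate import build_table4, event_rate, load_params
from .phenotype import (SurveillanceMode, concordance_triage, note_code_set,
                        phenotype_cohort, apply_inclusion)
from .scores import recommend, risk_profile
from .simulate import SimConfig, generate_cohort, write_dataset
from .stats import (cohens_kappa, compare_concordance,
                    compare_predictive_values, discordant_counts,
                    icc_two_way_random, ordinal_concordance,
                    paired_confusion, paired_proportion_test)
from .terminology import load_hierarchy, load_lexicon

log = logging.getLogger("nvafsurv")

STAGES = ("simulate", "extract", "phenotype", "score", "compare",
          "extrapolate")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("out")
    sim: SimConfig = field(default_factory=SimConfig)
    lexicon_path: Path | None = None     # None -> shipped fixture
    hierarchy_path: Path | None = None
    params_path: Path | None = None
    seed: int = 7
    n_boot: int = 2000
    chads_threshold: int = 2
    has_bled_threshold: int = 3
    stages: tuple[str, ...] = STAGES
    write_mentions: bool = False

    def validate(self) -> None:
        for p in (self.lexicon_path, self.hierarchy_path, self.params_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured file missing: {p}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.sim.seed = self.seed
        self.sim.validate()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns a bundle of DataFrames/paths."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = [f"nvafsurv {__version__} seed={cfg.seed}"]
    lex = (load_lexicon(cfg.lexicon_path) if cfg.lexicon_path
           else default_lexicon())
    hier = (load_hierarchy(cfg.hierarchy_path) if cfg.hierarchy_path
            else default_hierarchy())
    bundle: dict = {"out_dir": out}

    def stage(name: str):
        return name in cfg.stages

    try:
        name = "simulate"
        if stage(name):
            t0 = time.perf_counter()
            patients, gold = generate_cohort(cfg.sim)
            write_dataset(patients, gold, out / "dataset")
            bundle["patients"], bundle["gold"] = patients, gold
            run_log.append(f"simulate: n={len(patients)} "
                           f"gold_nvaf={int(gold['nvaf'].sum())} "
                           f"({time.perf_counter()-t0:.2f}s)")
            log.info(run_log[-1])

        name = "extract"
        if stage(name) and "patients" in bundle:
            t0 = time.perf_counter()
            note_codes = {p.patient_id: note_code_set(p, lex)
                          for p in bundle["patients"]}
            bundle["note_codes"] = note_codes
            if cfg.write_mentions:
                with open(out / "mentions.jsonl", "w", encoding="utf-8") as fh:
                    for p in bundle["patients"]:
                        for note in p.notes:
                            for m in extract_mentions(note.text, lex):
                                fh.write(json.dumps({
                                    "patient_id": p.patient_id,
                                    "date": note.date, "code": m.code,
                                    "system": m.system,
                                    "start": m.char_span[0],
                                    "end": m.char_span[1],
                                    "negated": m.negated}) + "\n")
            n_codes = sum(len(v) for v in note_codes.values())
            run_log.append(f"extract: {n_codes} note-derived codes "
                           f"({time.perf_counter()-t0:.2f}s)")
            log.info(run_log[-1])

        name = "phenotype"
        if stage(name) and "patients" in bundle:
            t0 = time.perf_counter()
            pheno = phenotype_cohort(bundle["patients"], lex, hier)
            wide = pheno.pivot(index="patient_id", columns="mode",
                               values="nvaf").rename(
                columns={"structured": "structured_nvaf",
                         "combined": "combined_nvaf"})
            wide["triage"] = [
                concordance_triage(bool(s), bool(c)).value
                for s, c in zip(wide["structured_nvaf"],
                                wide["combined_nvaf"])]
            pheno = pheno.merge(wide["triage"].reset_index(),
                                on="patient_id")
            pheno.to_csv(out / "phenotype.csv", index=False)
            bundle["phenotype"] = pheno
            n = len(bundle["patients"])
            inc = pheno[pheno["mode"] == "combined"]["included"]
            n_inc, n_exc = int(inc.sum()), int((~inc).sum())
            assert n_inc + n_exc == n, "attrition accounting mismatch"
            run_log.append(
                f"phenotype: {n} screened = {n_inc} included + {n_exc} "
                f"excluded; structured_nvaf="
                f"{int(wide['structured_nvaf'].sum())} combined_nvaf="
                f"{int(wide['combined_nvaf'].sum())} "
                f"({time.perf_counter()-t0:.2f}s)")
            log.info(run_log[-1])

        name = "score"
        if stage(name) and "patients" in bundle:
            t0 = time.perf_counter()
            rows = []
            for p in bundle["patients"]:
                if not apply_inclusion(p):
                    continue
                nc = bundle.get("note_codes", {}).get(p.patient_id)
                for mode in SurveillanceMode:
                    prof = risk_profile(p, mode, lex, hier, note_codes=nc)
                    rec, high_bleed = recommend(prof)
                    rows.append({
                        "patient_id": p.patient_id, "mode": mode.value,
                        "chads_vasc": prof.chads_vasc,
                        "has_bled": prof.has_bled,
                        "contraindicated": prof.contraindicated,
                        "on_oac": prof.on_oac,
                        "recommendation": rec.value,
                        "high_bleed_risk": high_bleed})
            scores = pd.DataFrame(rows)
            scores.to_csv(out / "scores.csv", index=False)
            bundle["scores"] = scores
            run_log.append(f"score: {len(scores)} (patient, mode) profiles "
                           f"({time.perf_counter()-t0:.2f}s)")
            log.info(run_log[-1])

        name = "compare"
        if stage(name) and {"phenotype", "scores", "gold"} <= bundle.keys():
            t0 = time.perf_counter()
            bundle["comparison"] = _compare_stage(bundle, cfg, out)
            run_log.append(f"compare: done ({time.perf_counter()-t0:.2f}s)")
            log.info(run_log[-1])

        name = "extrapolate"
        if stage(name):
            t0 = time.perf_counter()
            params_path = cfg.params_path or data_path("params.yaml")
            rates, cp, national = load_params(params_path)
            table4 = build_table4(
                rates, cp,
                national_pop=national.get("population", 316_005_000),
                structured_needing=national.get("structured_needing",
                                                3_009_840),
                combined_needing=national.get("combined_needing", 3_976_057),
                nvaf_populations=tuple(national.get(
                    "nvaf_populations", (4_955_284, 6_545_930))),
                eligible_populations=tuple(national.get(
                    "eligible_populations", (4_543_995, 6_002_707))))
            bundle["table4"] = table4
            bundle["claims"] = (rates, cp)
            table4.to_frame().to_csv(out / "table4.csv", index=False)
            run_log.append(f"extrapolate: strokes prevented "
                           f"{table4.combined['strokes_prevented']} "
                           f"({time.perf_counter()-t0:.2f}s)")
            log.info(run_log[-1])
    except Exception as exc:  # partial outputs retained on disk
        (out / "run.log").write_text("\n".join(run_log) + f"\nFAILED: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(name, exc) from exc

    (out / "run.log").write_text("\n".join(run_log) + "\n")
    return bundle


def _mode_frame(bundle: dict) -> pd.DataFrame:
    """Included patients with gold labels and per-mode NVAF flags/scores."""
    pheno = bundle["phenotype"]
    gold = bundle["gold"]
    scores = bundle["scores"]
    nvaf = pheno.pivot(index="patient_id", columns="mode", values="nvaf")
    inc = pheno.pivot(index="patient_id", columns="mode", values="included")
    sc = scores.pivot(index="patient_id", columns="mode",
                      values=["chads_vasc", "has_bled"])
    sc.columns = [f"{a}_{b}" for a, b in sc.columns]
    df = gold.set_index("patient_id").join(
        nvaf.rename(columns={"structured": "structured_nvaf",
                             "combined": "combined_nvaf"})).join(sc)
    df["included"] = inc["combined"].reindex(df.index).fillna(False)
    return df[df["included"].astype(bool)].copy()


def _compare_stage(bundle: dict, cfg: PipelineConfig, out: Path) -> dict:
    df = _mode_frame(bundle)
    results: dict = {}
    seed = cfg.seed

    # --- case finding (binary NVAF) -------------------------------------
    g = df["nvaf"].astype(bool).to_numpy()
    s = df["structured_nvaf"].astype(bool).to_numpy()
    c = df["combined_nvaf"].astype(bool).to_numpy()
    t1_rows = []
    for mode, pred in (("structured", s), ("combined", c)):
        m = paired_confusion(g, pred)
        t1_rows.append({"mode": mode, "sensitivity": m.sensitivity,
                        "specificity": m.specificity, "ppv": m.ppv,
                        "npv": m.npv, "f_score": m.f_score,
                        "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn})
    table1 = pd.DataFrame(t1_rows)
    table1.to_csv(out / "table1.csv", index=False)
    results["table1"] = table1

    # --- score-level comparisons (ordinal, thresholded) ------------------
    candidate = df[s | c | g]
    t2_rows = []
    for score_name, threshold in (("chads_vasc", cfg.chads_threshold),
                                  ("has_bled", cfg.has_bled_threshold)):
        gold_scores = candidate[
            "gold_chads_vasc" if score_name == "chads_vasc"
            else "gold_has_bled"].to_numpy()
        s_scores = candidate[f"{score_name}_structured"].to_numpy()
        c_scores = candidate[f"{score_name}_combined"].to_numpy()
        gb = gold_scores >= threshold
        sb = s_scores >= threshold
        cb = c_scores >= threshold
        ms = paired_confusion(gb, sb)
        mc = paired_confusion(gb, cb)
        b, cc = discordant_counts(gb, sb, cb, among="positive")
        sens_test = paired_proportion_test(b, cc)
        b2, cc2 = discordant_counts(gb, sb, cb, among="negative")
        spec_test = paired_proportion_test(b2, cc2)
        ppv_res, npv_res = compare_predictive_values(gb, sb, cb)
        kap_s = cohens_kappa(gb, sb, n_boot=cfg.n_boot, seed=seed)
        kap_c = cohens_kappa(gb, cb, n_boot=cfg.n_boot, seed=seed + 1)
        icc_s = icc_two_way_random(
            np.column_stack([gold_scores, s_scores]),
            n_boot=cfg.n_boot, seed=seed + 2)
        icc_c = icc_two_way_random(
            np.column_stack([gold_scores, c_scores]),
            n_boot=cfg.n_boot, seed=seed + 3)
        conc_s = ordinal_concordance(s_scores, gold_scores)
        conc_c = ordinal_concordance(c_scores, gold_scores)
        comp = compare_concordance(c_scores, s_scores, gold_scores)
        t2_rows.append({
            "score": score_name,
            "sens_structured": ms.sensitivity, "sens_combined": mc.sensitivity,
            "sens_stat": sens_test.statistic, "sens_p": sens_test.p_value,
            "sens_method": sens_test.method.value,
            "spec_structured": ms.specificity, "spec_combined": mc.specificity,
            "spec_stat": spec_test.statistic, "spec_p": spec_test.p_value,
            "spec_method": spec_test.method.value,
            "ppv_structured": ms.ppv, "ppv_combined": mc.ppv,
            "ppv_stat": ppv_res.statistic, "ppv_p": ppv_res.p_value,
            "npv_structured": ms.npv, "npv_combined": mc.npv,
            "npv_stat": npv_res.statistic, "npv_p": npv_res.p_value,
            "kappa_structured": kap_s.estimate,
            "kappa_structured_lo": kap_s.ci[0],
            "kappa_structured_hi": kap_s.ci[1],
            "kappa_combined": kap_c.estimate,
            "kappa_combined_lo": kap_c.ci[0],
            "kappa_combined_hi": kap_c.ci[1],
            "icc_structured": icc_s.estimate, "icc_combined": icc_c.estimate,
            "c_index_structured": conc_s.c_index,
            "c_index_combined": conc_c.c_index,
            "somers_d_structured": conc_s.somers_d,
            "somers_d_combined": conc_c.somers_d,
            "concordance_z": comp.z, "concordance_p": comp.p_value,
        })
    table2 = pd.DataFrame(t2_rows)
    table2.to_csv(out / "table2.csv", index=False)
    results["table2"] = table2
    return results


def render_report(bundle: dict, out_dir: str | Path | None = None) -> Path:
    """Write table3.csv (claims cascade and event rates) and a plain-text
    summary of whatever stage outputs are present; missing stages are
    skipped with a warning."""
    out = Path(out_dir or bundle.get("out_dir", "out"))
    out.mkdir(parents=True, exist_ok=True)
    lines = ["nvafsurv report", "=" * 40]
    if "claims" in bundle:
        rates, _cp = bundle["claims"]
        rows = []
        for name, (num, den) in rates.counts.items():
            decimals = 2 if name == "stroke_death_risk" else 1
            rows.append({"rate": name, "numerator": num, "denominator": den,
                         "event_rate_pct": event_rate(num, den, decimals)})
        table3 = pd.DataFrame(rows)
        table3.to_csv(out / "table3.csv", index=False)
        lines.append("claims event rates written to table3.csv")
    else:
        log.warning("claims rates missing; table3 skipped")
        lines.append("WARNING: table3 skipped (no claims rates)")
    for key, fname in (("comparison", "table1/table2"), ("table4", "table4")):
        if key not in bundle:
            log.warning("%s missing; %s skipped", key, fname)
            lines.append(f"WARNING: {fname} skipped (stage not run)")
        else:
            lines.append(f"{fname} written")
    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
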