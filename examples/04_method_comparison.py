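"""Compare the two surveillance modes against the synthetic gold standard.

Reports case-finding accuracy (sensitivity/PPV/F per mode), the paired
tests on score-level accuracy (McNemar or exact binomial for sensitivity
and specificity, the generalized score statistic for predictive values),
and ordinal concordance of the 0-9 risk scores (C index, Somers' D, and
the paired Z comparison).
"""

from nvafsurv import SimConfig
from nvafsurv.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/example_compare", sim=SimConfig(n_patients=2000, seed=42),
    seed=42, n_boot=1000,
    stages=("simulate", "extract", "phenotype", "score", "compare"))
bundle = run_pipeline(cfg)

t1 = bundle["comparison"]["table1"].set_index("mode")
print("NVAF case finding vs gold standard:")
for mode in ("structured", "combined"):
    r = t1.loc[mode]
    print(f"  {mode:>10s}: sens {r.sensitivity:.3f}  ppv {r.ppv:.3f}  "
          f"F {r.f_score:.3f}")

t2 = bundle["comparison"]["table2"].set_index("score")
for score in ("chads_vasc", "has_bled"):
    r = t2.loc[score]
    print(f"\n{score} (threshold {'>=2' if score == 'chads_vasc' else '>=3'}):")
    print(f"  sensitivity {r.sens_structured:.3f} -> {r.sens_combined:.3f} "
          f"({r.sens_method}, p={r.sens_p:.3g})")
    print(f"  NPV {r.npv_structured:.3f} -> {r.npv_combined:.3f} "
          f"(generalized score {r.npv_stat:.2f}, p={r.npv_p:.3g})")
    print(f"  C index {r.c_index_structured:.3f} -> {r.c_index_combined:.3f}"
          f"  Somers' D {r.somers_d_structured:.3f} -> "
          f"{r.somers_d_combined:.3f}  (Z={r.concordance_z:.2f})")

print("\nAdding note-derived concepts roughly doubles case-finding "
      "sensitivity while\nkeeping PPV high, and the combined scores are "
      "more concordant with truth.")
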