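"""Detection-aware differential abundance with planted-truth scoring.

Runs the five-step procedure (G test on detection counts, conditional
minimum-value imputation, moderated paired t-test, BH FDR, log2FC-z
thresholds) on a planted cohort and scores the calls against the
generator's truth.
"""

from plaqueomics import (
    CohortConfig, differential_analysis, filter_contaminants,
    filter_min_detection, generate_cohort, median_normalize,
)
from plaqueomics.simulate import score_dap_recovery

cfg = CohortConfig(n_proteins=1500, n_pairs_per_age=20, ages=(3,),
                   frac_dap=0.05, effect_size=2.0, frac_late=0.0,
                   frac_decline=0.0, n_blocks=0, block_size=0,
                   plaque_linked_blocks=0, n_tracer_followers=0, seed=2)
matrix, truth = generate_cohort(cfg)
m = median_normalize(filter_min_detection(filter_contaminants(matrix)))

res = differential_analysis(m, fdr_threshold=0.05, z_threshold=2.5)
n_dap = int(res["is_dap"].sum())
n_imputed = int((res["imputed_count"] > 0).sum())
print(f"tested {int(res['tested'].sum())} proteins; {n_dap} DAP calls; "
      f"{n_imputed} proteins received detection-equalizing imputation")

score = score_dap_recovery(res, truth, cfg.effect_size)
print(f"sensitivity {score['sensitivity']:.3f}, empirical FDR {score['fdr']:.3f} "
      f"against {score['n_true']} planted plaque-enriched proteins")
print("\nA sensitivity near 1 with empirical FDR near the nominal 0.05 shows "
      "the moderated test plus z-filter recovers the planted enrichment.")
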