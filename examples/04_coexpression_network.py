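"""Planar filtered co-expression network with modules, hubs and traits.

Builds the permutation-screened correlation network on a cohort with
five planted 20-protein blocks (one carrying the plaque effect),
detects modules against a random-planar-graph null, and correlates
module eigengenes with the plaque indicator.
"""

from plaqueomics import (
    CohortConfig, filter_contaminants, filter_min_detection, generate_cohort,
    median_normalize,
)
from plaqueomics.network import (
    build_pfn, detect_modules, find_hubs, module_trait_correlation,
    reported_modules, significant_correlations,
)

cfg = CohortConfig(n_proteins=400, n_pairs_per_age=20, frac_dap=0.0,
                   frac_late=0.0, frac_decline=0.0, n_tracer_followers=0,
                   n_blocks=5, block_size=20, block_rho=0.8,
                   plaque_linked_blocks=1, seed=4)
matrix, truth = generate_cohort(cfg)
m = median_normalize(filter_min_detection(filter_contaminants(matrix)))

edges = significant_correlations(m, n_perm=20, fdr=0.05, seed=4)
print(f"{len(edges.edges)} significant edges at permutation FDR 0.05 "
      f"(|rho| threshold {edges.threshold:.3f})")

pfn = build_pfn(edges)
print(f"PFN: {pfn.number_of_nodes()} nodes, {pfn.number_of_edges()} edges "
      f"(planar bound {3 * (pfn.number_of_nodes() - 2)})")

modules = detect_modules(pfn, min_size=10, n_null=60, seed=5)
report = reported_modules(modules)
module_trait_correlation(report, m)
print(f"{len(report)} reported modules (size 10..|V|/2):")
for mod in report:
    find_hubs(pfn, mod, n_null=500, seed=6)
    flag = "plaque-associated" if mod.trait_associated else ""
    print(f"  {mod.module_id}: size {mod.size:3d}, trait_r {mod.trait_r:+.2f}, "
          f"{len(mod.hubs)} hubs {flag}")
print("\nThe module overlapping the plaque-linked block should carry "
      "trait_r > 0.4; pure co-abundance blocks should not.")
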