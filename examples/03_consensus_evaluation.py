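"""Multi-model consensus: intersect candidate lists and rank the models.

Runs the permutation test under three scoring systems, selects candidates
at p <= 0.01 per model, then prints the exact-subset intersection table,
each model's consensus fraction and its combined rank against the truth
set of planted drivers.
"""

from smds import (
    CohortSpec,
    assign_snvs,
    evaluate_models,
    intersect_models,
    run_gene_tests,
    select_candidates,
    simulate_cohort,
)
from smds.consensus import evaluations_to_frame

cohort = simulate_cohort(CohortSpec(n_genes=30, n_driver_genes=5, n_samples=30, flank=500, seed=9))
assignment = assign_snvs(cohort.snvs, cohort.regions)
results = run_gene_tests(
    cohort.regions, assignment, list(cohort.score_sets.values()),
    trials=500, global_seed=2, indexes=cohort.indexes,
)

by_score = {}
for r in results:
    by_score.setdefault(r.score_name, []).append(r)
candidate_sets = [select_candidates(rs, alpha=0.01) for rs in by_score.values()]

table = intersect_models(candidate_sets)
print("genes selected by exactly these models:")
print(table.to_frame().to_string(index=False))

evaluations = evaluate_models(candidate_sets, truth_genes=cohort.driver_genes)
print("\nmodel evaluation (overlap with truth, consensus, average rank):")
print(evaluations_to_frame(evaluations).to_string(index=False))
# consensus = fraction of a model's candidates also called by >= 2 other
# models; the final ordering averages the truth-overlap and consensus ranks.
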