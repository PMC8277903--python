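"""Simulate a planted cohort and classify SV-gene pairs end to end.

A small synthetic cohort with pathogenic SVs planted across active-domain
boundaries; the pipeline builds pairs, labels them from expression outliers,
and evaluates the per-SV-type MILES + random-forest models with
leave-one-patient-out cross-validation.
"""

import logging

from tadmil import SimConfig, run_study, simulate_cohort, simulate_reference

logging.basicConfig(level=logging.WARNING)

config = SimConfig(n_patients=16, svs_per_patient={"DEL": 2, "DUP": 2})
genome = simulate_reference(config, seed=7)
cohort = simulate_cohort(config, genome, seed=8)
print(f"{len(cohort.svs)} SVs -> {len(cohort.pairs)} SV-gene pairs, "
      f"{len(cohort.truth)} planted pathogenic pairs")

result = run_study(
    cohort.svs, genome.domains, genome.genes, genome.elements, genome.tracks,
    cohort.expression, cohort.mutation_index, seed=9, pairs=cohort.pairs,
)
for sv_type, auc in sorted(result.auc.items()):
    bundle = result.bundles[sv_type]
    recall = result.truth_recall(cohort.truth, sv_type)
    print(
        f"{sv_type}: LOPO AUC={auc:.3f} operating_point={bundle.operating_point:.3f} "
        f"planted-truth recall={recall:.2f}"
    )

# AUC near 1 would mean labels are perfectly predictable from the gained/lost
# elements; ~0.13 of background pairs are expression outliers by chance, so
# values in the low-to-mid 0.9s indicate the planted signal is recovered.
# The operating point is the probability above which a pair is called
# pathogenic (max recall at precision >= 0.5 on pooled CV predictions).
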