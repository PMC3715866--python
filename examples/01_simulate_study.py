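"""Generate a seeded synthetic study: a high-CNA tumour cohort and a
47-line cell-line panel of three archetypes, with ground-truth labels.

Run:  python examples/01_simulate_study.py
"""

import linematch as lm

cohort = lm.generate_tumour_cohort(lm.CohortSpec(), seed=1)
matrix = lm.map_segments_to_genes(cohort.profiles, cohort.gene_models)
mean_profile = lm.mean_cna_profile(matrix, list(matrix.columns))
panel = lm.generate_cell_line_panel(
    lm.PanelSpec(), mean_profile, cohort.gene_models, seed=2,
    tumour_expression_loadings=cohort.expression_loadings,
)

print(f"tumours:     {len(cohort.profiles)} profiles, "
      f"{len(cohort.mutations)} mutation records, "
      f"{cohort.expression.values.shape[0]} expression genes")
print(f"cell lines:  {len(panel.profiles)} profiles; archetypes: "
      f"{panel.truth['archetype'].value_counts().to_dict()}")
print(f"TP53 mutated in {cohort.truth['tp53_mutated'].mean():.0%} of tumours "
      f"({(~cohort.truth['flat_wt']).sum()} non-flat, "
      f"{cohort.truth['flat_wt'].sum()} flat TP53-wild-type outliers)")
# The truth tables carry the planted labels every downstream example can be
# checked against; all artefacts pass the io validators unchanged.
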