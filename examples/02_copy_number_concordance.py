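"""Copy-number concordance: fraction genome altered, gene-level mapping and
the three similarity summaries of one cell line against the cohort.

Run:  python examples/02_copy_number_concordance.py
"""

import numpy as np

import linematch as lm

cohort = lm.generate_tumour_cohort(lm.CohortSpec(), seed=1)
tum_matrix = lm.map_segments_to_genes(cohort.profiles, cohort.gene_models)
mean_profile = lm.mean_cna_profile(tum_matrix, list(tum_matrix.columns))
panel = lm.generate_cell_line_panel(lm.PanelSpec(), mean_profile, cohort.gene_models, seed=2)
cell_matrix = lm.map_segments_to_genes(panel.profiles, cohort.gene_models)

thr = lm.Thresholds()  # FGA threshold 0.2 for tumours, 0.3 for cell lines
fga = [lm.fraction_genome_altered(p, thr.fga_tumour) for p in cohort.profiles]
print(f"median tumour FGA at T={thr.fga_tumour}: {np.median(fga):.3f}")

for sid in ("LINE00", "LINE46"):  # an HGSOC-like line and a hypermutator
    sim = lm.cna_similarity(cell_matrix[sid], tum_matrix, mean_profile, cell_line=sid)
    arch = panel.truth.set_index("sample_id").loc[sid, "archetype"]
    print(f"{sid} ({arch}): corr with mean profile A = {sim.corr_with_mean_profile:.3f}, "
          f"median per-tumour r = {sim.median_correlation:.3f}, "
          f"best single tumour r = {sim.max_single_tumour_correlation:.3f}")
# A near 1 marks a profile that recapitulates the cohort's recurrent gains
# and losses; a flat profile scores near 0 on all three summaries.
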