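"""Assemble the suitability score S = A + 0.5*B - 0.5*C - 0.25*D for every
cell line and produce the good/moderate/poor grouping.

Run:  python examples/04_suitability_ranking.py
"""

import numpy as np
import pandas as pd

import linematch as lm

cohort = lm.generate_tumour_cohort(lm.CohortSpec(), seed=1)
tum_matrix = lm.map_segments_to_genes(cohort.profiles, cohort.gene_models)
mean_profile = lm.mean_cna_profile(tum_matrix, list(tum_matrix.columns))
panel = lm.generate_cell_line_panel(lm.PanelSpec(), mean_profile, cohort.gene_models, seed=2)
cell_matrix = lm.map_segments_to_genes(panel.profiles, cohort.gene_models)

functional = lm.filter_functional(panel.mutations)
burdens = [lm.mutation_frequency(functional, t) for t in panel.coverage]
fga = {p.sample_id: lm.fraction_genome_altered(p, 0.3) for p in panel.profiles}
hyper = lm.classify_hypermutated(burdens, fga)
universe = set(cohort.gene_models["gene"])

components = []
for p in panel.profiles:
    sid = p.sample_id
    sim = lm.cna_similarity(cell_matrix[sid], tum_matrix, mean_profile, cell_line=sid)
    markers = lm.marker_status(sid, functional, gene_cna=cell_matrix[sid],
                               gene_universe=universe)
    components.append(lm.assemble_components(sid, sim, markers, bool(hyper[sid])))

ranking = lm.rank_and_tier(components)  # top 12 good, bottom 12 poor
table = ranking.to_frame().merge(
    panel.truth[["sample_id", "archetype"]], left_on="sample", right_on="sample_id"
)
print(table[["sample", "A", "B", "C", "D", "S", "tier", "archetype"]]
      .round(3).head(5).to_string(index=False))
print("...")
print(table[["sample", "A", "B", "C", "D", "S", "tier", "archetype"]]
      .round(3).tail(5).to_string(index=False))
good = table[table["tier"] == "good"]
print(f"\ngood tier: {len(good)} lines, "
      f"{(good['archetype'] == 'hgsoc_like').mean():.0%} HGSOC-like")
# High A with a TP53 mutation lifts a line to the top; hypermutation (C)
# and non-HGSOC panel mutations (D) push it down.
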