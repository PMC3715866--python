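"""Coverage-corrected mutation burden and hypermutator outliers.

Functional mutation frequency = likely-functional mutations / covered bases,
per Mb; samples combining high frequency with a flat copy-number profile are
the hypermutator archetype.

Run:  python examples/03_mutation_burden.py
"""

import numpy as np

import linematch as lm

cohort = lm.generate_tumour_cohort(lm.CohortSpec(), seed=1)
matrix = lm.map_segments_to_genes(cohort.profiles, cohort.gene_models)
mean_profile = lm.mean_cna_profile(matrix, list(matrix.columns))
panel = lm.generate_cell_line_panel(lm.PanelSpec(), mean_profile, cohort.gene_models, seed=2)

functional = lm.filter_functional(panel.mutations)  # drops silent/non-coding
burdens = [lm.mutation_frequency(functional, track) for track in panel.coverage]
fga = {p.sample_id: lm.fraction_genome_altered(p, 0.3) for p in panel.profiles}
hyper = lm.classify_hypermutated(burdens, fga)  # freq > 10/Mb and FGA < 0.25

freqs = np.array([b.frequency_per_mb for b in burdens])
print(f"median cell-line burden: {np.median(freqs):.2f} functional mutations/Mb")
print(f"hypermutators called: {sorted(hyper[hyper].index)}")
truth = panel.truth.set_index("sample_id")
for sid in hyper[hyper].index:
    b = next(x for x in burdens if x.sample_id == sid)
    print(f"  {sid}: {b.frequency_per_mb:.1f}/Mb over {b.bases_covered/1e6:.0f} Mb, "
          f"FGA {fga[sid]:.3f} (truth: {truth.loc[sid, 'archetype']})")
# The five flagged lines combine many mutations with few copy-number
# changes, the opposite of the high-CNA / low-burden tumour genotype.
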