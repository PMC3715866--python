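import numpy as np
import pandas as pd
import pytest

import linematch as lm


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_profile():
    """Three 100-bp segments on chromosome 1 with mixed alteration signs."""
    seg = pd.DataFrame(
        {
            "chromosome": ["1", "1", "1"],
            "start": [1, 101, 201],
            "end": [100, 200, 300],
            "seg_mean": [0.5, 0.1, -0.4],
        }
    )
    return lm.SegmentedProfile(sample_id="S1", segments=seg)


def random_profile(rng, sample_id="R1", n_segments=50, max_len=80):
    """Non-overlapping random segments with small coordinates, per-base testable."""
    rows = []
    for chrom in ("1", "2"):
        cursor = 1
        for _ in range(n_segments // 2):
            length = int(rng.integers(2, max_len))
            rows.append((chrom, cursor, cursor + length - 1, float(rng.normal(0, 0.5))))
            cursor += length + int(rng.integers(0, 5))
    return lm.SegmentedProfile(
        sample_id=sample_id,
        segments=pd.DataFrame(rows, columns=["chromosome", "start", "end", "seg_mean"]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return lm.generate_tumour_cohort(lm.CohortSpec(n_tumours=30, n_genes=440), seed=7)


@pytest.fixture(scope="session")
def small_cohort_matrix(small_cohort):
    matrix = lm.map_segments_to_genes(small_cohort.profiles, small_cohort.gene_models)
    mean_profile = lm.mean_cna_profile(matrix, list(matrix.columns))
    return matrix, mean_profile


@pytest.fixture(scope="session")
def small_panel(small_cohort, small_cohort_matrix):
    _, mean_profile = small_cohort_matrix
    return lm.generate_cell_line_panel(
        lm.PanelSpec(),
        mean_profile,
        small_cohort.gene_models,
        seed=11,
        tumour_expression_loadings=small_cohort.expression_loadings,
    )
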