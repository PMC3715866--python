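"""Copy-number operations against direct evaluation and per-base oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

import linematch as lm
from linematch.io import ValidationError

from conftest import random_profile


def per_base_expansion(profile):
    """Oracle: explicit (chromosome, position) -> seg_mean map, one entry per base."""
    values = {}
    for row in profile.segments.itertuples():
        for pos in range(row.start, row.end + 1):
            values[(row.chromosome, pos)] = row.seg_mean
    return values


class TestFga:
    def test_direct_evaluation(self, tiny_profile):
        # lengths 100/100/100, |CN| = 0.5, 0.1, 0.4; T = 0.2 keeps two segments
        assert lm.fraction_genome_altered(tiny_profile, 0.2) == pytest.approx(200 / 300)

    def test_boundaries(self):
        flat = lm.SegmentedProfile(
            "F",
            pd.DataFrame(
                {"chromosome": ["1"], "start": [1], "end": [1000], "seg_mean": [0.0]}
            ),
        )
        assert lm.fraction_genome_altered(flat, 0.2) == 0.0
        hot = lm.SegmentedProfile(
            "H",
            pd.DataFrame(
                {"chromosome": ["1", "2"], "start": [1, 1], "end": [10, 20],
                 "seg_mean": [2.0, -1.5]}
            ),
        )
        assert lm.fraction_genome_altered(hot, 0.3) == 1.0

    def test_threshold_is_strict(self):
        prof = lm.SegmentedProfile(
            "T",
            pd.DataFrame(
                {"chromosome": ["1"], "start": [1], "end": [100], "seg_mean": [0.2]}
            ),
        )
        assert lm.fraction_genome_altered(prof, 0.2) == 0.0

    def test_errors(self, tiny_profile):
        with pytest.raises(ValueError, match="positive"):
            lm.fraction_genome_altered(tiny_profile, 0.0)
        empty = lm.SegmentedProfile("E", tiny_profile.segments.iloc[:0])
        with pytest.raises(ValidationError, match="empty"):
            lm.fraction_genome_altered(empty, 0.2)

    def test_matches_per_base_tally_on_random_profile(self, rng):
        prof = random_profile(rng, n_segments=1000, max_len=40)
        base = per_base_expansion(prof)
        for t in (0.1, 0.3, 0.5):
            altered = sum(1 for v in base.values() if abs(v) > t)
            assert lm.fraction_genome_altered(prof, t) == pytest.approx(
                altered / len(base), abs=1e-12
            )

    def test_non_increasing_in_threshold(self, rng):
        prof = random_profile(rng, n_segments=200)
        grid = np.linspace(0.05, 1.5, 20)
        fga = [lm.fraction_genome_altered(prof, t) for t in grid]
        assert all(0.0 <= f <= 1.0 for f in fga)
        assert all(a >= b for a, b in zip(fga, fga[1:]))


class TestGeneMapping:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])

    def test_gene_inside_single_segment(self):
        prof = lm.SegmentedProfile(
            "S",
            pd.DataFrame(
                {"chromosome": ["1"], "start": [1], "end": [1000], "seg_mean": [0.7]}
            ),
        )
        genes = self._genes([("G1", "1", 100, 199)])
        mat = lm.map_segments_to_genes([prof], genes)
        assert mat.loc["G1", "S"] == pytest.approx(0.7)

    def test_length_weighted_mean_across_breakpoint(self):
        # gene covers 100 bp: 25 in the first segment, 75 in the second
        prof = lm.SegmentedProfile(
            "S",
            pd.DataFrame(
                {"chromosome": ["1", "1"], "start": [1, 126], "end": [125, 400],
                 "seg_mean": [0.0, 0.4]}
            ),
        )
        genes = self._genes([("G1", "1", 101, 200)])
        mat = lm.map_segments_to_genes([prof], genes)
        assert mat.loc["G1", "S"] == pytest.approx(0.25 * 0.0 + 0.75 * 0.4)

    def test_uncovered_gene_is_missing(self):
        prof = lm.SegmentedProfile(
            "S",
            pd.DataFrame(
                {"chromosome": ["1"], "start": [1], "end": [100], "seg_mean": [0.7]}
            ),
        )
        genes = self._genes([("G1", "2", 10, 50), ("G2", "1", 200, 300)])
        mat = lm.map_segments_to_genes([prof], genes)
        assert mat["S"].isna().all()

    def test_matches_per_base_overlap_oracle(self, rng):
        profiles = [random_profile(rng, sample_id=f"S{i}", n_segments=60, max_len=50)
                    for i in range(8)]
        genes = []
        for g in range(120):
            chrom = "1" if g % 2 == 0 else "2"
            start = int(rng.integers(1, 1200))
            genes.append((f"G{g:03d}", chrom, start, start + int(rng.integers(2, 60))))
        gene_tab = self._genes(genes)
        mat = lm.map_segments_to_genes(profiles, gene_tab)
        for prof in profiles:
            base = per_base_expansion(prof)
            for row in gene_tab.itertuples():
                vals = [
                    base[(row.chromosome, p)]
                    for p in range(row.start, row.end + 1)
                    if (row.chromosome, p) in base
                ]
                got = mat.loc[row.gene, prof.sample_id]
                if not vals:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(np.mean(vals), abs=1e-10)

    def test_largest_overlap_rule(self):
        prof = lm.SegmentedProfile(
            "S",
            pd.DataFrame(
                {"chromosome": ["1", "1"], "start": [1, 126], "end": [125, 400],
                 "seg_mean": [0.0, 0.4]}
            ),
        )
        genes = self._genes([("G1", "1", 101, 200)])
        mat = lm.map_segments_to_genes([prof], genes, rule="largest_overlap")
        assert mat.loc["G1", "S"] == pytest.approx(0.4)


class TestMeanProfile:
    def test_mean_and_missing_rule(self):
        mat = pd.DataFrame({"t1": [0.2, np.nan], "t2": [0.6, 0.5]}, index=["g1", "g2"])
        mean = lm.mean_cna_profile(mat, ["t1", "t2"])
        assert mean["g1"] == pytest.approx(0.4)
        assert mean["g2"] == pytest.approx(0.5)  # mean of present values only

    def test_all_missing_gene_absent(self):
        mat = pd.DataFrame({"t1": [np.nan], "t2": [np.nan]}, index=["g1"])
        assert "g1" not in lm.mean_cna_profile(mat, ["t1", "t2"]).index

    def test_empty_cohort_rejected(self):
        mat = pd.DataFrame({"t1": [0.1]}, index=["g1"])
        with pytest.raises(ValidationError, match="empty"):
            lm.mean_cna_profile(mat, [])

    def test_matches_brute_force(self, rng):
        mat = pd.DataFrame(
            rng.normal(size=(500, 6)),
            index=[f"g{i}" for i in range(500)],
            columns=[f"t{i}" for i in range(6)],
        )
        mean = lm.mean_cna_profile(mat, list(mat.columns))
        for g in mat.index[:50]:
            assert mean[g] == pytest.approx(np.mean(mat.loc[g]), abs=1e-12)


class TestSimilarity:
    def _setup(self, rng, n_genes=80, n_tumours=12):
        genes = [f"g{i}" for i in range(n_genes)]
        mat = pd.DataFrame(
            rng.normal(size=(n_genes, n_tumours)),
            index=genes,
            columns=[f"t{i}" for i in range(n_tumours)],
        )
        return genes, mat

    def test_identical_to_one_tumour(self, rng):
        genes, mat = self._setup(rng)
        mean = lm.mean_cna_profile(mat, list(mat.columns))
        sim = lm.cna_similarity(mat["t3"].copy(), mat, mean, cell_line="x")
        assert sim.per_tumour_correlations["t3"] == pytest.approx(1.0)
        assert sim.max_single_tumour_correlation == pytest.approx(1.0)

    def test_anti_correlated_with_mean(self, rng):
        genes, mat = self._setup(rng)
        mean = lm.mean_cna_profile(mat, list(mat.columns))
        sim = lm.cna_similarity(-mean, mat, mean, cell_line="x")
        assert sim.corr_with_mean_profile == pytest.approx(-1.0)

    def test_median_is_brute_force_median_of_pearson(self, rng):
        genes, mat = self._setup(rng, n_genes=60, n_tumours=15)
        vec = pd.Series(rng.normal(size=60), index=genes)
        mean = lm.mean_cna_profile(mat, list(mat.columns))
        sim = lm.cna_similarity(vec, mat, mean, cell_line="x")
        oracle = [pearsonr(vec.to_numpy(), mat[t].to_numpy())[0] for t in mat.columns]
        assert sim.median_correlation == pytest.approx(np.median(oracle), abs=1e-12)
        assert sim.max_single_tumour_correlation == pytest.approx(max(oracle), abs=1e-12)
        assert (
            min(oracle) <= sim.median_correlation <= max(oracle)
        )

    def test_gene_order_permutation_invariant(self, rng):
        genes, mat = self._setup(rng)
        vec = pd.Series(rng.normal(size=len(genes)), index=genes)
        mean = lm.mean_cna_profile(mat, list(mat.columns))
        a = lm.cna_similarity(vec, mat, mean, cell_line="x")
        perm = list(rng.permutation(genes))
        b = lm.cna_similarity(vec.loc[perm], mat.loc[perm], mean.loc[perm], cell_line="x")
        assert a.corr_with_mean_profile == pytest.approx(b.corr_with_mean_profile, abs=1e-12)
        assert a.median_correlation == pytest.approx(b.median_correlation, abs=1e-12)

    def test_zero_variance_tumour_excluded_with_warning(self, rng):
        genes, mat = self._setup(rng)
        mat["t0"] = 0.7  # constant: correlation undefined
        vec = pd.Series(rng.normal(size=len(genes)), index=genes)
        mean = lm.mean_cna_profile(mat, list(mat.columns))
        with pytest.warns(UserWarning, match="undefined"):
            sim = lm.cna_similarity(vec, mat, mean, cell_line="x")
        assert np.isnan(sim.per_tumour_correlations["t0"])
        assert not np.isnan(sim.median_correlation)

    def test_too_few_shared_genes_rejected(self, rng):
        genes, mat = self._setup(rng)
        vec = pd.Series([0.1, 0.2], index=["g0", "g1"])
        mean = lm.mean_cna_profile(mat, list(mat.columns))
        with pytest.raises(ValidationError, match="fewer than"):
            lm.cna_similarity(vec, mat, mean, cell_line="x")


@pytest.mark.parametrize(
    "value,threshold,expected",
    [(1.2, 1.0, True), (1.0, 1.0, False), (-2.0, 1.0, False), (0.35, 0.3, True)],
)
def test_high_level_amplification_strict_inequality(value, threshold, expected):
    assert lm.call_high_level_amplification(value, threshold) is expected
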