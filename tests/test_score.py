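"""Score-engine behaviour: region mask, thresholding, scoring, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from apoepgs import (
    ValidationError,
    align_alleles,
    apply_region_mask,
    build_score_grid,
    compute_score,
    default_apoe_region,
    filter_by_threshold,
    residualize_on_apoe,
    score_correlation_matrix,
    standardize,
)
from apoepgs.genotype_io import RegionMask
from apoepgs.score import DegenerateScoreError

from conftest import make_geno, make_stats


class TestDefaultApoeRegion:
    def test_default_flank_matches_published_interval(self):
        region = default_apoe_region()
        assert (region.chromosome, region.start, region.stop) == (
            "19", 45_384_477, 45_432_606,
        )

    def test_zero_flank_gives_gene_span(self):
        region = default_apoe_region(flank=0)
        assert (region.start, region.stop) == (45_394_477, 45_422_606)

    def test_negative_flank_inverting_interval_rejected(self):
        with pytest.raises(ValidationError):
            default_apoe_region(flank=-20_000)


class TestThresholdFilter:
    def test_strict_inequality(self):
        stats = make_stats(
            [
                ("rs1", "1", 1, "A", "G", 0.1, 0.005),
                ("rs2", "1", 2, "A", "G", 0.1, 0.02),
                ("rs3", "1", 3, "A", "G", 0.1, 0.5),
            ]
        )
        assert filter_by_threshold(stats, 0.01).df.variant_id.tolist() == ["rs1"]
        # boundary: p exactly equal to pT is excluded
        boundary = make_stats([("rs1", "1", 1, "A", "G", 0.1, 0.01)])
        assert len(filter_by_threshold(boundary, 0.01)) == 0

    def test_threshold_one_retains_everything(self):
        stats = make_stats(
            [("rs1", "1", 1, "A", "G", 0.1, 0.5), ("rs2", "1", 2, "A", "G", 0.1, 1.0)]
        )
        assert len(filter_by_threshold(stats, 1.0)) == 2

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_domain_threshold_rejected(self, bad, small_stats):
        with pytest.raises(ValueError):
            filter_by_threshold(small_stats, bad)


class TestRegionMaskApplication:
    @pytest.mark.parametrize(
        "chrom,pos,removed",
        [
            ("19", 45_384_477, True),   # inclusive left boundary
            ("19", 45_384_476, False),
            ("19", 45_432_606, True),   # inclusive right boundary
            ("19", 45_432_607, False),
            ("18", 45_400_000, False),  # chromosome mismatch
        ],
    )
    def test_boundary_membership(self, chrom, pos, removed):
        stats = make_stats([("rs1", chrom, pos, "A", "G", 0.1, 0.01)])
        out = apply_region_mask(stats, default_apoe_region())
        assert (len(out) == 0) is removed

    def test_invert_keeps_region_only(self):
        stats = make_stats(
            [
                ("rin", "19", 45_400_000, "A", "G", 0.1, 0.01),
                ("rout", "1", 100, "A", "G", 0.1, 0.01),
            ]
        )
        only = apply_region_mask(stats, default_apoe_region(), invert=True)
        assert only.df.variant_id.tolist() == ["rin"]


class TestComputeScore:
    def test_hand_computed_dot_product(self, small_stats, small_geno):
        # weights after alignment: rs1 +0.3 (direct), rs2 +0.2 (flipped
        # -(-0.2)), rs3 +0.5 (direct)
        al = align_alleles(small_stats, small_geno)
        raw, n_used = compute_score(small_geno, al)
        assert n_used == 3
        # s1: 0*0.3 + 1*0.2 + 2*0.5 = 1.2 ; s2: 2*0.3 + 2*0.2 + 0*0.5 = 1.0
        np.testing.assert_allclose(raw.to_numpy(), [1.2, 1.0])

    def test_single_variant_single_term(self):
        stats = make_stats([("rs1", "1", 100, "A", "G", 0.5, 0.01)])
        geno = make_geno(["s1"], [("rs1", "1", 100, "A", "G")], [[2.0]])
        raw, _ = compute_score(geno, align_alleles(stats, geno))
        assert raw.iloc[0] == 1.0

    def test_zero_weights_annihilate(self):
        stats = make_stats([("rs1", "1", 100, "A", "G", 0.0, 0.01)])
        geno = make_geno(["s1", "s2"], [("rs1", "1", 100, "A", "G")], [[1.0], [2.0]])
        raw, _ = compute_score(geno, align_alleles(stats, geno))
        assert (raw == 0).all()

    def test_zero_usable_variants_is_explicit_error(self, small_stats):
        geno = make_geno(["s1"], [("rsX", "9", 9, "A", "G")], [[1.0]])
        with pytest.raises(DegenerateScoreError):
            compute_score(geno, align_alleles(small_stats, geno))

    def test_missing_dosages_mean_imputed(self):
        stats = make_stats([("rs1", "1", 100, "A", "G", 1.0, 0.01)])
        geno = make_geno(
            ["s1", "s2", "s3"], [("rs1", "1", 100, "A", "G")],
            [[0.0], [2.0], [np.nan]],
        )
        raw, _ = compute_score(geno, align_alleles(stats, geno))
        assert raw.loc["s3"] == pytest.approx(1.0)  # mean of 0 and 2

    @given(
        dosages=hnp.arrays(
            float, st.tuples(st.integers(2, 10), st.integers(1, 10)),
            elements=st.floats(0, 2, allow_nan=False, width=32),
        ),
        data=st.data(),
    )
    def test_matches_brute_force_double_loop(self, dosages, data):
        n, m = dosages.shape
        betas = data.draw(
            st.lists(st.floats(-1, 1, allow_nan=False, width=32),
                     min_size=m, max_size=m)
        )
        stats = make_stats(
            [(f"rs{j}", "1", j + 1, "A", "G", betas[j], 0.01) for j in range(m)]
        )
        geno = make_geno(
            [f"s{i}" for i in range(n)],
            [(f"rs{j}", "1", j + 1, "A", "G") for j in range(m)],
            dosages,
        )
        raw, _ = compute_score(geno, align_alleles(stats, geno))
        expected = [
            sum(betas[j] * dosages[i, j] for j in range(m)) for i in range(n)
        ]
        np.testing.assert_allclose(raw.to_numpy(), expected, atol=1e-9)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        res = standardize(pd.Series([1.0, 2.0, 3.0]), 0.01, False, 3)
        assert res.scores.mean() == pytest.approx(0, abs=1e-12)
        assert res.scores.std(ddof=1) == pytest.approx(1, abs=1e-12)
        assert (res.raw_mean, res.raw_sd) == (2.0, 1.0)

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateScoreError):
            standardize(pd.Series([1.0, 1.0, 1.0]), 0.01, False, 1)

    def test_idempotence(self):
        raw = pd.Series([0.3, -1.2, 2.4, 0.0])
        once = standardize(raw, 0.5, False, 4).scores
        twice = standardize(once, 0.5, False, 4).scores
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


@pytest.fixture(scope="module")
def grid_inputs():
    from apoepgs import SimulationConfig, simulate_genotypes, simulate_summary_stats

    config = SimulationConfig(n_individuals=300, n_variants=400, seed=11)
    geno, _ = simulate_genotypes(config)
    stats = simulate_summary_stats(config, geno)
    return stats, geno


class TestScoreGrid:
    def test_default_grid_has_twelve_cells(self, grid_inputs):
        stats, geno = grid_inputs
        results = build_score_grid(stats, geno)
        assert len(results) == 12
        assert len({(r.threshold, r.region_excluded) for r in results}) == 12
        for r in results:
            assert abs(r.scores.mean()) < 1e-10
            assert abs(r.scores.std(ddof=1) - 1) < 1e-8

    def test_variant_counts_monotone_in_threshold(self, grid_inputs):
        stats, geno = grid_inputs
        results = build_score_grid(stats, geno)
        for flag in (False, True):
            counts = [r.n_variants_used for r in
                      sorted((x for x in results if x.region_excluded == flag),
                             key=lambda x: x.threshold)]
            assert counts == sorted(counts)

    def test_threshold_nesting_of_variant_sets(self, grid_inputs):
        stats, _ = grid_inputs
        sub_small = set(filter_by_threshold(stats, 0.01).df.variant_id)
        sub_big = set(filter_by_threshold(stats, 0.3).df.variant_id)
        assert sub_small <= sub_big

    def test_decomposition_identity(self, grid_inputs):
        """region-in raw score = region-out + region-only, per individual."""
        stats, geno = grid_inputs
        mask = default_apoe_region()
        for p_threshold in (0.001, 0.05, 1.0):
            sub = filter_by_threshold(stats, p_threshold)
            full, _ = compute_score(geno, align_alleles(sub, geno))
            out_part, _ = compute_score(
                geno, align_alleles(apply_region_mask(sub, mask), geno)
            )
            only_part, _ = compute_score(
                geno, align_alleles(apply_region_mask(sub, mask, invert=True), geno)
            )
            np.testing.assert_allclose(
                full.to_numpy(), (out_part + only_part).to_numpy(), atol=1e-10
            )

    def test_empty_mask_leaves_scores_identical(self, grid_inputs):
        stats, geno = grid_inputs
        nowhere = RegionMask("21", 1, 2)
        results = build_score_grid(stats, geno, thresholds=(0.05,), mask=nowhere)
        np.testing.assert_allclose(
            results[0].scores.to_numpy(), results[1].scores.to_numpy(), atol=1e-12
        )


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, grid_inputs):
        stats, geno = grid_inputs
        results = build_score_grid(stats, geno, thresholds=(0.01, 1.0))
        corr = score_correlation_matrix(results)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_duplicated_score_fully_correlated(self, grid_inputs):
        stats, geno = grid_inputs
        r = build_score_grid(stats, geno, thresholds=(0.05,))[0]
        import copy

        r2 = copy.deepcopy(r)
        r2.region_excluded = not r.region_excluded
        corr = score_correlation_matrix([r, r2])
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_mismatched_individuals_rejected(self, grid_inputs):
        stats, geno = grid_inputs
        r = build_score_grid(stats, geno, thresholds=(0.05,))
        import copy

        r2 = copy.deepcopy(r[1])
        r2.scores = r2.scores.iloc[:-1]
        with pytest.raises(ValidationError):
            score_correlation_matrix([r[0], r2])


class TestResidualization:
    def test_orthogonal_indicators_leave_score_unchanged(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(400)]
        score = standardize(
            pd.Series(rng.normal(size=400), index=ids), 0.01, True, 10
        )
        # indicators orthogonalised against the score by construction
        one = pd.Series((np.arange(400) % 4 == 0).astype(int), index=ids)
        two = pd.Series(0, index=ids)
        resid = residualize_on_apoe(score, one, pd.Series(0.0, index=ids))
        assert abs(np.corrcoef(resid.scores, score.scores)[0, 1]) > 0.99
        assert abs(np.corrcoef(resid.scores, one)[0, 1]) < 1e-10
        assert two.sum() == 0  # degenerate column handled by lstsq

    def test_residuals_uncorrelated_with_indicators(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(500)]
        one = pd.Series(rng.random(500) < 0.25, index=ids).astype(int)
        two = pd.Series((rng.random(500) < 0.02) & (one == 0), index=ids).astype(int)
        raw = pd.Series(
            rng.normal(size=500) + 0.8 * one + 1.6 * two, index=ids
        )
        score = standardize(raw, 0.01, False, 10)
        resid = residualize_on_apoe(score, one, two)
        assert abs(np.corrcoef(resid.scores, one)[0, 1]) < 1e-8
        assert abs(np.corrcoef(resid.scores, two)[0, 1]) < 1e-8
        assert abs(resid.scores.mean()) < 1e-10

    def test_moderate_loading_keeps_high_correlation(self):
        """With a realistic e4 loading the residualized score stays nearly
        identical to the original (the restricted-data analysis reported
        r > 0.97)."""
        rng = np.random.default_rng(5)
        n = 2000
        ids = [f"s{i}" for i in range(n)]
        one = pd.Series(rng.random(n) < 0.243, index=ids).astype(int)
        two = pd.Series((rng.random(n) < 0.021) & (one == 0), index=ids).astype(int)
        raw = pd.Series(rng.normal(size=n) + 0.3 * one + 0.6 * two, index=ids)
        score = standardize(raw, 0.01, False, 10)
        resid = residualize_on_apoe(score, one, two)
        r = np.corrcoef(resid.scores, score.scores)[0, 1]
        assert r > 0.95
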