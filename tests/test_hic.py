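import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from telodisjoin import genome as gm
from telodisjoin import hic, simulate
from telodisjoin.hic import ContactMatrix


def one_chrom_matrix(values, resolution=10):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return ContactMatrix(resolution, [("chrA", n * resolution)], values)


def two_chrom_matrix(values, nb=(3, 4), resolution=10):
    values = np.asarray(values, dtype=float)
    chroms = [("chrA", nb[0] * resolution), ("chrB", nb[1] * resolution)]
    return ContactMatrix(resolution, chroms, values)


def random_symmetric(rng, n, nan_frac=0.0):
    m = rng.random((n, n)) * 10
    m = (m + m.T) / 2
    if nan_frac:
        mask = rng.random((n, n)) < nan_frac
        mask = mask | mask.T
        m[mask] = np.nan
    return m


def oracle_vc_sqrt(matrix):
    """Brute-force VC_SQRT: explicit row sums and per-entry division."""
    n = matrix.shape[0]
    r = np.array([np.nansum(matrix[i]) for i in range(n)])
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if r[i] > 0 and r[j] > 0 and not np.isnan(matrix[i, j]):
                out[i, j] = matrix[i, j] / np.sqrt(r[i] * r[j])
            elif r[i] > 0 and r[j] > 0:
                out[i, j] = np.nan
    return out


def oracle_oe(m: ContactMatrix):
    """Brute-force O/E: enumerate every diagonal of every chromosome."""
    out = np.full_like(m.matrix, np.nan)
    slices = m.chrom_slices
    max_nb = max(m.bins_per_chrom)
    expected = {}
    for d in range(max_nb):
        vals = []
        for sl in slices.values():
            block = m.matrix[sl, sl]
            nb = block.shape[0]
            for i in range(nb):
                for j in range(nb):
                    if abs(i - j) == d and not np.isnan(block[i, j]):
                        vals.append(block[i, j])
        expected[d] = np.mean(vals) if vals else np.nan
    for sl in slices.values():
        block = m.matrix[sl, sl]
        nb = block.shape[0]
        for i in range(nb):
            for j in range(nb):
                e = expected[abs(i - j)]
                out[sl.start + i, sl.start + j] = (
                    block[i, j] / e if e and not np.isnan(block[i, j]) else np.nan
                )
    inter_vals = []
    names = list(slices)
    intra = m.intra_mask()
    for i in range(m.n_bins):
        for j in range(m.n_bins):
            if not intra[i, j] and not np.isnan(m.matrix[i, j]):
                inter_vals.append(m.matrix[i, j])
    inter_mean = np.mean(inter_vals) if inter_vals else np.nan
    for i in range(m.n_bins):
        for j in range(m.n_bins):
            if not intra[i, j] and not np.isnan(m.matrix[i, j]):
                out[i, j] = m.matrix[i, j] / inter_mean
    return out


class TestVcSqrt:
    def test_hand_computed_3x3(self):
        m = one_chrom_matrix([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        out = hic.vc_sqrt_normalize(m)
        expected = np.array(
            [[0.5, 0.25, 0.25], [0.25, 0.5, 0.25], [0.25, 0.25, 0.5]]
        )
        np.testing.assert_allclose(out.matrix, expected, atol=1e-12)
        assert out.state == "vc_sqrt"

    def test_constant_matrix_gives_one_over_n(self):
        for n in (3, 7, 12):
            m = one_chrom_matrix(np.full((n, n), 4.2))
            np.testing.assert_allclose(
                hic.vc_sqrt_normalize(m).matrix, 1.0 / n, atol=1e-12
            )

    def test_scale_invariance(self, rng):
        for _ in range(100):
            base = random_symmetric(rng, int(rng.integers(3, 12)))
            k = float(rng.random() * 10 + 0.1)
            a = hic.vc_sqrt_normalize(one_chrom_matrix(base)).matrix
            b = hic.vc_sqrt_normalize(one_chrom_matrix(base * k)).matrix
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_marginal_rows_masked(self):
        values = np.array([[1.0, 0, 1], [0, 0, 0], [1, 0, 1]])
        out = hic.vc_sqrt_normalize(one_chrom_matrix(values))
        assert np.isnan(out.matrix[1]).all()
        assert np.isnan(out.matrix[:, 1]).all()
        assert np.isfinite(out.matrix[0, 0])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            base = random_symmetric(rng, 8, nan_frac=0.1)
            got = hic.vc_sqrt_normalize(one_chrom_matrix(base)).matrix
            np.testing.assert_allclose(got, oracle_vc_sqrt(base), atol=1e-9)

    def test_non_symmetric_rejected(self):
        values = np.array([[1.0, 2], [3, 4]])
        with pytest.raises(ValueError, match="not symmetric"):
            hic.vc_sqrt_normalize(one_chrom_matrix(values))

    def test_requires_raw_state(self):
        m = one_chrom_matrix(np.ones((3, 3)))
        m.state = "vc_sqrt"
        with pytest.raises(ValueError, match="raw"):
            hic.vc_sqrt_normalize(m)


class TestObservedExpected:
    def test_constant_per_diagonal_gives_unity(self, rng):
        n = 8
        values = np.zeros((n, n))
        diag_values = rng.random(n) + 0.5
        for d in range(n):
            for i in range(n - d):
                values[i, i + d] = values[i + d, i] = diag_values[d]
        out = hic.observed_over_expected(one_chrom_matrix(values))
        np.testing.assert_allclose(out.matrix, 1.0, atol=1e-12)

    def test_masking_respected(self):
        values = np.full((4, 4), 2.0)
        values[0, 3] = values[3, 0] = np.nan
        out = hic.observed_over_expected(one_chrom_matrix(values))
        assert np.isnan(out.matrix[0, 3]) and np.isnan(out.matrix[3, 0])
        assert np.isfinite(out.matrix[0, 2])

    def test_two_chromosome_brute_force_oracle(self, rng):
        for _ in range(10):
            base = random_symmetric(rng, 7, nan_frac=0.1)
            m = two_chrom_matrix(base, nb=(3, 4))
            got = hic.observed_over_expected(m).matrix
            np.testing.assert_allclose(got, oracle_oe(m), atol=1e-9, equal_nan=True)

    def test_inter_entries_divided_by_pooled_mean(self):
        base = np.ones((7, 7))
        base[:3, 3:] = 2.0
        base[3:, :3] = 2.0
        m = two_chrom_matrix(base, nb=(3, 4))
        out = hic.observed_over_expected(m)
        np.testing.assert_allclose(out.matrix[:3, 3:], 1.0, atol=1e-12)


class TestDistanceDecay:
    def test_flat_matrix_flat_series(self):
        m = one_chrom_matrix(np.full((10, 10), 3.0))
        curve = hic.distance_decay_curve(m)
        assert np.allclose(curve["median"], 3.0)
        assert curve["probability"].sum() == pytest.approx(1.0)

    def test_monotone_decay_non_increasing(self, hic_genome):
        params = simulate.HiCSimParams(
            decay_exponent=-1.2, telomere_gain_intra=1.0, telomere_gain_inter=1.0,
            centromere_gain=1.0, noise="none",
        )
        m = simulate.simulate_hic(hic_genome, params)
        curve = hic.distance_decay_curve(m)
        assert np.all(np.diff(curve["median"]) <= 1e-12)

    def test_recovers_planted_exponent(self, hic_genome):
        params = simulate.HiCSimParams(
            decay_exponent=-1.0, telomere_gain_intra=1.0, telomere_gain_inter=1.0,
            centromere_gain=1.0, noise="none",
        )
        m = simulate.simulate_hic(hic_genome, params)
        curve = hic.distance_decay_curve(hic.vc_sqrt_normalize(m))
        slope = hic.fit_decay_exponent(curve, min_bp=25_000, max_bp=400_000)
        assert -1.1 <= slope <= -0.9

    def test_log_binned_variant(self, hic_genome):
        m = simulate.simulate_hic(
            hic_genome, simulate.HiCSimParams(read_pairs=200_000), seed=0
        )
        curve = hic.distance_decay_curve(m, n_log_bins=12)
        assert len(curve) <= 12
        assert curve["probability"].sum() == pytest.approx(1.0)


class TestDifferentialMap:
    def test_equal_inputs_all_zero(self, rng):
        base = random_symmetric(rng, 5)
        a = one_chrom_matrix(base)
        b = one_chrom_matrix(base.copy())
        np.testing.assert_allclose(hic.differential_map(a, b, eps=1.0).matrix, 0.0)

    def test_doubled_input_gives_one_at_zero_eps(self, rng):
        base = random_symmetric(rng, 5) + 1.0
        out = hic.differential_map(
            one_chrom_matrix(base * 2), one_chrom_matrix(base), eps=0.0
        )
        np.testing.assert_allclose(out.matrix, 1.0, atol=1e-12)

    def test_hand_computed_4x4_with_eps_one(self):
        a = np.array([[3.0, 1, 0, 7], [1, 3, 1, 0], [0, 1, 3, 1], [7, 0, 1, 3]])
        b = np.array([[1.0, 0, 1, 3], [0, 1, 0, 1], [1, 0, 1, 0], [3, 1, 0, 1]])
        out = hic.differential_map(one_chrom_matrix(a), one_chrom_matrix(b), eps=1.0)
        np.testing.assert_allclose(out.matrix, np.log2((a + 1) / (b + 1)), atol=1e-12)

    def test_mask_propagates_from_either_input(self):
        a = np.full((3, 3), 2.0)
        b = np.full((3, 3), 2.0)
        a[0, 1] = a[1, 0] = np.nan
        out = hic.differential_map(one_chrom_matrix(a), one_chrom_matrix(b), eps=1.0)
        assert np.isnan(out.matrix[0, 1])

    def test_geometry_mismatch_rejected(self):
        a = one_chrom_matrix(np.ones((3, 3)))
        b = one_chrom_matrix(np.ones((4, 4)))
        with pytest.raises(ValueError, match="geometry"):
            hic.differential_map(a, b)

    def test_default_eps_is_smallest_positive_control_value(self, rng):
        base = random_symmetric(rng, 4) + 0.5
        base[0, 0] = 0.25
        out = hic.differential_map(
            one_chrom_matrix(base * 2), one_chrom_matrix(base)
        )
        expected = np.log2((base * 2 + 0.25) / (base + 0.25))
        np.testing.assert_allclose(out.matrix, expected, atol=1e-12)


class TestRankQuantize:
    def test_simple_triplet(self):
        np.testing.assert_allclose(
            hic.rank_quantize(np.array([[1.0, 2.0, 3.0]])), [[0.0, 0.5, 1.0]]
        )

    def test_hand_ranked_ties_2x2(self):
        # [5, 5, 9, 1] -> ranks {2.5, 2.5, 4, 1} -> [0.5, 0.5, 1.0, 0.0]
        out = hic.rank_quantize(np.array([[5.0, 5.0], [9.0, 1.0]]))
        np.testing.assert_allclose(out, [[0.5, 0.5], [1.0, 0.0]])

    def test_monotone_transform_invariance(self, rng):
        for _ in range(100):
            w = rng.random((5, 5)) * 10
            np.testing.assert_allclose(
                hic.rank_quantize(w), hic.rank_quantize(np.exp(w)), atol=1e-12
            )

    @given(
        w=arrays(
            np.float64,
            (4, 4),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_output_in_unit_interval(self, w):
        out = hic.rank_quantize(w)
        assert np.nanmin(out) >= 0.0 and np.nanmax(out) <= 1.0

    def test_distribution_free_sorted_values(self, rng):
        # tie-free windows always quantize to the same sorted sequence
        expected = np.arange(9) / 8.0
        for _ in range(10):
            w = rng.permutation(rng.normal(size=9) * 100).reshape(3, 3)
            np.testing.assert_allclose(np.sort(hic.rank_quantize(w), axis=None), expected)

    def test_all_missing_window(self):
        out = hic.rank_quantize(np.full((3, 3), np.nan))
        assert np.isnan(out).all()

    def test_constant_window_all_ties(self):
        np.testing.assert_allclose(hic.rank_quantize(np.full((2, 3), 7.0)), 0.5)

    def test_too_small_window_rejected(self):
        with pytest.raises(ValueError):
            hic.rank_quantize(np.array([1.0]))


def build_aggregation_genome():
    # two chromosomes of 10 and 12 bins at 5 kb, centromeres mid-chromosome
    chroms = [("chrA", 50_000), ("chrB", 60_000)]
    g = gm.GenomeModel("target", chroms)
    g.features = [
        gm.FeatureRecord("chrA", 20_000, 25_000, "centromere", "cenA"),
        gm.FeatureRecord("chrB", 25_000, 30_000, "centromere", "cenB"),
    ]
    return g


def oracle_telomere_frames(m, genome, region_bp, window, step):
    """Naive reference for the pair aggregation: explicit loops with
    orientation handling and intra symmetrization."""
    res = m.resolution
    k = region_bp // res
    slices = m.chrom_slices
    regions = []
    for name, _length in genome.chromosomes:
        sl = slices[name]
        regions.append((name, "left", list(range(sl.start, sl.start + k))))
        regions.append((name, "right", list(range(sl.stop - 1, sl.stop - 1 - k, -1))))
    frames = {"intra": [], "inter": []}
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            chrom_a, _, bins_a = regions[a]
            chrom_b, _, bins_b = regions[b]
            cls = "intra" if chrom_a == chrom_b else "inter"
            sub = np.empty((k, k))
            for i, bi in enumerate(bins_a):
                for j, bj in enumerate(bins_b):
                    sub[i, j] = m.matrix[bi, bj]
            if cls == "intra":
                sub = (sub + sub.T) / 2.0
            for r in range(0, k - window + 1, step):
                for c in range(0, k - window + 1, step):
                    frames[cls].append(sub[r : r + window, c : c + window])
    return frames


class TestTelomereAggregate:
    def test_frame_count_formula(self, hic_genome):
        m = simulate.simulate_hic(
            hic_genome, simulate.HiCSimParams(read_pairs=100_000), seed=0
        )
        stacks, excluded = hic.telomere_aggregate(m, hic_genome, 150_000, 21, 1)
        # 30x30 regions, 21x21 window, step 1 -> (30-21+1)^2 = 100 frames/pair
        assert stacks["intra"].n_frames == 3 * 100
        assert stacks["inter"].n_frames == 12 * 100
        assert not excluded

    def test_constant_matrix_quantized_uniform_half(self, hic_genome):
        n = sum(-(-l // 5000) for _, l in hic_genome.chromosomes)
        m = ContactMatrix(5000, list(hic_genome.chromosomes), np.full((n, n), 2.0))
        stacks, _ = hic.telomere_aggregate(m, hic_genome, 150_000, 21, 1)
        for stack in stacks.values():
            np.testing.assert_allclose(stack.aggregate(), 2.0)
            np.testing.assert_allclose(stack.quantized, 0.5)

    def test_matches_brute_force_oracle(self, rng):
        g = build_aggregation_genome()
        n = 10 + 12
        m = ContactMatrix(5_000, list(g.chromosomes), random_symmetric(rng, n))
        region_bp, window, step = 20_000, 3, 1
        stacks, _ = hic.telomere_aggregate(m, g, region_bp, window, step)
        expected = oracle_telomere_frames(m, g, region_bp, window, step)
        for cls in ("intra", "inter"):
            got = stacks[cls].windows
            want = np.stack(expected[cls])
            assert got.shape == want.shape
            np.testing.assert_allclose(got, want, atol=1e-9)
            np.testing.assert_allclose(
                stacks[cls].aggregate(), want.mean(axis=0), atol=1e-9
            )

    def test_truncated_pairs_excluded_and_reported(self, rng):
        # chrShort holds 2 bins, fewer than the 3-bin window
        g = gm.GenomeModel("target", [("chrA", 50_000), ("chrShort", 10_000)])
        n = 10 + 2
        m = ContactMatrix(5_000, list(g.chromosomes), random_symmetric(rng, n))
        stacks, excluded = hic.telomere_aggregate(m, g, region_bp=20_000, window=3)
        assert excluded  # every pair touching chrShort
        assert all(
            "chrShort" in (p.region_a.chrom, p.region_b.chrom) for p in excluded
        )
        assert stacks["intra"].n_pairs == 1  # chrA's own pair survives

    def test_planted_corner_signal_localizes(self, hic_genome):
        hits = 0
        n_seeds = 10
        params = simulate.wildtype_hic_params(read_pairs=2_000_000)
        for seed in range(n_seeds):
            m = simulate.simulate_hic(hic_genome, params, seed=seed)
            oe = hic.observed_over_expected(hic.vc_sqrt_normalize(m))
            stacks, _ = hic.telomere_aggregate(oe, hic_genome)
            for cls in ("intra", "inter"):
                agg = stacks[cls].aggregate()
                hits += np.unravel_index(np.nanargmax(agg), agg.shape) == (0, 0)
        assert hits >= int(0.9 * 2 * n_seeds)

    def test_orientation_invariance(self, rng):
        # reversing a chromosome's stored orientation (flipping its bins in
        # the matrix) leaves class aggregates unchanged
        g = build_aggregation_genome()
        n = 22
        base = random_symmetric(rng, n)
        m = ContactMatrix(5_000, list(g.chromosomes), base)
        flipped = base.copy()
        sl = m.chrom_slices["chrA"]
        idx = np.arange(n)
        idx[sl] = idx[sl][::-1]
        flipped = flipped[np.ix_(idx, idx)]
        m_flip = ContactMatrix(5_000, list(g.chromosomes), flipped)
        a, _ = hic.telomere_aggregate(m, g, 20_000, 3, 1)
        b, _ = hic.telomere_aggregate(m_flip, g, 20_000, 3, 1)
        for cls in ("intra", "inter"):
            np.testing.assert_allclose(
                a[cls].aggregate(), b[cls].aggregate(), atol=1e-9
            )
            np.testing.assert_allclose(
                np.sort(a[cls].block_means("raw", 2)),
                np.sort(b[cls].block_means("raw", 2)),
                atol=1e-9,
            )

    def test_region_not_multiple_of_resolution_rejected(self, hic_genome):
        m = simulate.simulate_hic(
            hic_genome, simulate.HiCSimParams(read_pairs=10_000), seed=0
        )
        with pytest.raises(ValueError, match="multiple of the resolution"):
            hic.telomere_aggregate(m, hic_genome, region_bp=149_999)

    def test_window_larger_than_region_rejected(self, hic_genome):
        m = simulate.simulate_hic(
            hic_genome, simulate.HiCSimParams(read_pairs=10_000), seed=0
        )
        with pytest.raises(ValueError, match="smaller than the sliding window"):
            hic.telomere_aggregate(m, hic_genome, region_bp=50_000, window=21)


class TestCentromereAggregate:
    def test_builds_center_focused_stack(self, hic_genome):
        m = simulate.simulate_hic(
            hic_genome, simulate.HiCSimParams(read_pairs=500_000), seed=1
        )
        stack = hic.centromere_aggregate(m, hic_genome)
        assert stack.pair_class == "cen"
        assert stack.focus == "center"
        assert stack.n_pairs == 3  # C(3, 2)
        assert stack.n_frames == 300


class TestCompareConditions:
    def _stack_from_frames(self, frames, focus="corner"):
        frames = np.asarray(frames, dtype=float)
        quantized = np.stack([hic.rank_quantize(w) for w in frames])
        return hic.PairSubmatrixStack(
            pair_class="intra", windows=frames, quantized=quantized,
            n_pairs=1, window_size=frames.shape[1], step=1, focus=focus,
        )

    def test_self_comparison_p_one(self, rng):
        frames = rng.random((20, 6, 6))
        stack = self._stack_from_frames(frames)
        result = hic.compare_conditions(stack, self._stack_from_frames(frames), block=3)
        assert result.raw_test.p_value == 1.0
        assert result.quantized_test.p_value == 1.0

    def test_strict_dominance_hits_exact_enumeration_floor(self, rng):
        lo = self._stack_from_frames([rng.random((4, 4)) for _ in range(6)])
        hi = self._stack_from_frames([rng.random((4, 4)) + 10 for _ in range(6)])
        result = hic.compare_conditions(hi, lo, block=4, method="exact")
        # all a > b: exact two-sided p = 2 / C(12, 6)
        assert result.raw_test.p_value == pytest.approx(2 / 924, abs=1e-12)
        assert result.score_a > result.score_b

    def test_planted_gain_power(self, hic_genome):
        # one strong seed pair; the 100-seed stochastic version runs in the
        # acceptance suite
        from telodisjoin.pipeline import hic_discrimination_trial

        res = hic_discrimination_trial(0, genome=hic_genome)
        assert res["intra"].raw_test.p_value < 1e-3
        assert res["inter"].raw_test.p_value < 1e-3
        assert res["intra"].score_a > res["intra"].score_b

    def test_too_few_windows_rejected(self, rng):
        a = self._stack_from_frames(rng.random((1, 4, 4)))
        b = self._stack_from_frames(rng.random((5, 4, 4)))
        with pytest.raises(ValueError, match="fewer than 2 windows"):
            hic.compare_conditions(a, b, block=3)

    def test_mismatched_classes_rejected(self, rng):
        a = self._stack_from_frames(rng.random((5, 4, 4)))
        b = self._stack_from_frames(rng.random((5, 4, 4)))
        b.pair_class = "inter"
        with pytest.raises(ValueError, match="pair classes differ"):
            hic.compare_conditions(a, b)


class TestMatrixIO:
    def test_tsv_round_trip(self, hic_genome, tmp_path):
        m = simulate.simulate_hic(
            hic_genome, simulate.HiCSimParams(read_pairs=50_000), seed=0,
            condition="wt",
        )
        m.matrix[0, 1] = m.matrix[1, 0] = np.nan
        path = tmp_path / "matrix.tsv"
        hic.write_matrix_tsv(m, path)
        loaded = hic.read_matrix_tsv(path)
        assert loaded.resolution == m.resolution
        assert loaded.chromosomes == m.chromosomes
        assert loaded.condition == "wt"
        assert loaded.state == "raw"
        np.testing.assert_allclose(loaded.matrix, m.matrix, equal_nan=True)
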