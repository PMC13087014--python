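"""Tests for the donor-microarray processing chain."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from braintx import make_atlas, simulate_donors
from braintx.expression import (
    DonorSampleSet,
    ExpressionMatrix,
    aggregate_donors,
    assign_samples_to_regions,
    donor_region_matrix,
    filter_probes_by_intensity,
    gene_correlation_matrix,
    interpolate_empty_regions,
    normalize_srs,
    process_donors,
    select_probe_per_gene,
)


def _mini_donor(donor_id="D01", coords=None, intensities=None, background=None,
                probe_ids=("g1_p1",), probe_map=None):
    coords = np.zeros((3, 3)) if coords is None else np.asarray(coords, float)
    n = coords.shape[0]
    if intensities is None:
        intensities = np.ones((len(probe_ids), n))
    if background is None:
        background = np.zeros((len(probe_ids), n))
    if probe_map is None:
        probe_map = {p: p.split("_")[0] for p in probe_ids}
    return DonorSampleSet(donor_id, coords, probe_ids, intensities, background,
                          probe_map)


class TestProbeFilter:
    def test_probe_always_above_background_retained(self):
        d = _mini_donor(intensities=np.full((1, 3), 5.0),
                        background=np.full((1, 3), 1.0))
        retained, frac = filter_probes_by_intensity([d])
        assert retained == ["g1_p1"]
        assert frac["g1_p1"] == 0.0

    def test_exactly_half_below_is_discarded(self):
        # 2 of 4 pooled samples below background -> fraction 0.5 -> discarded
        intens = np.array([[0.0, 0.0, 5.0, 5.0]])
        bg = np.full((1, 4), 1.0)
        d = _mini_donor(coords=np.zeros((4, 3)), intensities=intens, background=bg)
        retained, frac = filter_probes_by_intensity([d])
        assert frac["g1_p1"] == 0.5
        assert retained == []

    def test_fractions_match_bruteforce(self, atlas58, rng):
        donors = simulate_donors(atlas58, 3, ["A", "B", "C"], probes_per_gene=4,
                                 weak_probe_fraction=0.25, seed=9)
        _, frac = filter_probes_by_intensity(donors)
        for k, p in enumerate(donors[0].probe_ids):
            count = total = 0
            for d in donors:
                for s in range(d.n_samples):
                    total += 1
                    if d.intensities[k, s] < d.background[k, s]:
                        count += 1
            assert frac[p] == pytest.approx(count / total)

    def test_mismatched_probe_sets_rejected(self):
        d1 = _mini_donor(probe_ids=("g1_p1",))
        d2 = _mini_donor(donor_id="D02", probe_ids=("g1_p2",))
        with pytest.raises(ValueError):
            filter_probes_by_intensity([d1, d2])


class TestProbeSelection:
    def _two_donor_pair(self, atlas, probe_intens_by_donor):
        donors = []
        for i, intens in enumerate(probe_intens_by_donor):
            donors.append(
                _mini_donor(
                    donor_id=f"D{i:02d}",
                    coords=atlas.centroids.copy(),
                    intensities=np.asarray(intens, float),
                    background=np.zeros_like(np.asarray(intens, float)),
                    probe_ids=("g1_p1", "g1_p2"),
                )
            )
        return donors

    def test_single_retained_probe_returned_with_nan_score(self, small_atlas):
        donors = [
            _mini_donor(donor_id=f"D{i}", coords=small_atlas.centroids.copy(),
                        intensities=np.ones((1, small_atlas.n_regions)))
            for i in range(2)
        ]
        sel = select_probe_per_gene(donors, ["g1_p1"], small_atlas)
        probe, score = sel["g1"]
        assert probe == "g1_p1"
        assert np.isnan(score)

    def test_consistent_probe_beats_noise(self, small_atlas, rng):
        n = small_atlas.n_regions
        signal = np.linspace(0, 1, n)
        wins = 0
        for rep in range(200):
            r = np.random.default_rng(rep)
            intens = []
            for _ in range(3):  # 3 donors
                pa = signal + r.normal(0, 0.01, n)  # consistent probe
                pb = r.normal(0, 1, n)  # pure noise
                intens.append(np.vstack([pa, pb]))
            donors = self._two_donor_pair(small_atlas, intens)
            sel = select_probe_per_gene(donors, ["g1_p1", "g1_p2"], small_atlas)
            wins += sel["g1"][0] == "g1_p1"
        assert wins >= 0.95 * 200

    def test_score_equals_hand_spearman(self):
        # two donors, 3-region profiles (1,2,3) vs (1,3,2): Spearman = 0.5
        atlas = make_atlas(3, 0, 0, 0, seed=1)
        intens = [
            np.vstack([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]),
            np.vstack([[1.0, 3.0, 2.0], [1.0, 3.0, 2.0]]),
        ]
        donors = self._two_donor_pair(atlas, intens)
        sel = select_probe_per_gene(donors, ["g1_p1", "g1_p2"], atlas)
        assert sel["g1"][1] == pytest.approx(0.5)

    def test_gene_without_probes_dropped_with_warning(self, small_atlas):
        donors = [
            _mini_donor(donor_id=f"D{i}", coords=small_atlas.centroids.copy(),
                        intensities=np.ones((2, small_atlas.n_regions)),
                        background=np.zeros((2, small_atlas.n_regions)),
                        probe_ids=("g1_p1", "g2_p1"))
            for i in range(2)
        ]
        with pytest.warns(UserWarning, match="g2"):
            sel = select_probe_per_gene(donors, ["g1_p1"], small_atlas)
        assert "g2" not in sel


class TestAssignment:
    def test_sample_at_centroid_assigned(self, small_atlas):
        d = _mini_donor(coords=small_atlas.centroids[[4]])
        asn = assign_samples_to_regions(d, small_atlas)
        assert asn[0] == 4

    def test_inclusive_2mm_threshold(self, small_atlas):
        target = small_atlas.centroids[2]
        # direction away from everything else still exactly 2.0 mm out
        offset = np.array([2.0, 0.0, 0.0])
        d = _mini_donor(coords=(target + offset)[None, :])
        asn = assign_samples_to_regions(d, small_atlas, tolerance=2.0)
        dists = np.linalg.norm(small_atlas.centroids - (target + offset), axis=1)
        assert dists.min() == pytest.approx(2.0)
        assert asn[0] == 2

    def test_far_sample_unassigned(self, small_atlas):
        far = small_atlas.centroids.mean(axis=0) + 500.0
        d = _mini_donor(coords=far[None, :])
        assert assign_samples_to_regions(d, small_atlas)[0] == -1

    def test_negative_tolerance_rejected(self, small_atlas):
        d = _mini_donor(coords=small_atlas.centroids[[0]])
        with pytest.raises(ValueError):
            assign_samples_to_regions(d, small_atlas, tolerance=-1)


class TestInterpolation:
    def test_no_empty_regions_is_identity(self, small_atlas):
        full = pd.DataFrame(
            np.random.default_rng(0).random((small_atlas.n_regions, 2)),
            index=list(small_atlas.region_ids), columns=["a", "b"],
        )
        out = interpolate_empty_regions(
            full, small_atlas.centroids, np.zeros((small_atlas.n_regions, 2)),
            small_atlas,
        )
        pd.testing.assert_frame_equal(out, full)

    def test_empty_region_filled_with_nearest_sample(self, small_atlas):
        n = small_atlas.n_regions
        rng = np.random.default_rng(3)
        coords = small_atlas.centroids[1:] + rng.normal(0, 0.5, (n - 1, 3))
        values = rng.random((n - 1, 2))
        partial = pd.DataFrame(
            np.vstack([[np.nan, np.nan], values]),
            index=list(small_atlas.region_ids), columns=["a", "b"],
        )
        out = interpolate_empty_regions(partial, coords, values, small_atlas)
        # brute-force nearest sample to region 0's centroid
        d = np.linalg.norm(coords - small_atlas.centroids[0], axis=1)
        assert np.allclose(out.iloc[0].to_numpy(), values[np.argmin(d)])
        assert not out.isna().any().any()

    def test_all_samples_one_location(self, small_atlas):
        coords = np.tile(small_atlas.centroids[0], (3, 1))
        values = np.tile([0.3, 0.7], (3, 1))
        partial = pd.DataFrame(
            np.full((small_atlas.n_regions, 2), np.nan),
            index=list(small_atlas.region_ids), columns=["a", "b"],
        )
        out = interpolate_empty_regions(partial, coords, values, small_atlas)
        assert np.allclose(out.to_numpy(), [0.3, 0.7])

    def test_no_samples_raises_with_donor_name(self, small_atlas):
        partial = pd.DataFrame(
            np.full((small_atlas.n_regions, 1), np.nan),
            index=list(small_atlas.region_ids), columns=["a"],
        )
        with pytest.raises(ValueError, match="D99"):
            interpolate_empty_regions(
                partial, np.empty((0, 3)), np.empty((0, 1)), small_atlas, "D99"
            )


class TestNormalizeSrs:
    def test_frozen_formula_example(self):
        # independently evaluated: x=(1..5), median 3, IQR 2 (linear-interp
        # quartiles), y = 1/(1+exp(-(x-3)*1.35/2)) then min-max rescaled
        out = normalize_srs(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]), axis=0)
        expected = [0.0, 0.2235541381, 0.5, 0.7764458619, 1.0]
        assert np.allclose(out[:, 0], expected, atol=1e-9)

    def test_output_in_unit_interval(self, rng):
        X = rng.normal(size=(30, 5)) * 10
        out = normalize_srs(X, axis=0)
        assert out.min() >= 0 and out.max() <= 1

    def test_rank_preserving(self, rng):
        x = np.sort(rng.normal(size=20))[:, None]
        out = normalize_srs(x, axis=0)[:, 0]
        assert (np.diff(out) > 0).all()

    def test_zero_iqr_rank_fallback(self):
        x = np.array([0.0, 1, 1, 1, 1, 1, 2])[:, None]
        assert np.percentile(x[:, 0], 75) - np.percentile(x[:, 0], 25) == 0
        out = normalize_srs(x, axis=0)[:, 0]
        assert out[0] == 0.0 and out[-1] == 1.0
        assert np.allclose(out[1:-1], 0.5)  # tied mid ranks

    def test_single_value_slice_passthrough(self):
        x = np.array([[5.0, 7.0]])
        out = normalize_srs(x, axis=1)  # 2 distinct values -> scaled
        assert np.allclose(out, [[0.0, 1.0]])
        const = np.array([[5.0, 5.0]])
        assert np.allclose(normalize_srs(const, axis=1), const)


class TestAggregateDonors:
    def test_single_donor_identity(self, rng):
        m = pd.DataFrame(rng.random((4, 3)))
        pd.testing.assert_frame_equal(aggregate_donors([m]), m)

    def test_symmetry(self, rng):
        v = pd.DataFrame(rng.random((4, 3)))
        w = 1.0 - v
        assert np.allclose(aggregate_donors([v, w]).to_numpy(), 0.5)

    def test_matches_elementwise_mean(self, rng):
        mats = [pd.DataFrame(rng.random((5, 4))) for _ in range(3)]
        out = aggregate_donors(mats).to_numpy()
        brute = np.zeros((5, 4))
        for i in range(5):
            for j in range(4):
                brute[i, j] = sum(m.iloc[i, j] for m in mats) / 3
        assert np.allclose(out, brute)

    def test_shape_mismatch_rejected(self, rng):
        a = pd.DataFrame(rng.random((3, 2)))
        b = pd.DataFrame(rng.random((4, 2)))
        with pytest.raises(ValueError):
            aggregate_donors([a, b])


class TestGeneCorrelation:
    def test_unit_diagonal_and_bounds(self, atlas58, expression12):
        corr = gene_correlation_matrix(expression12)
        assert np.allclose(np.diag(corr), 1.0)
        assert (corr.to_numpy() <= 1 + 1e-12).all()
        assert (corr.to_numpy() >= -1 - 1e-12).all()
        assert np.allclose(corr, corr.T)

    def test_duplicated_gene_perfect_correlation(self, atlas58, expression12):
        vals = np.column_stack([expression12.values[:, 0]] * 2)
        em = ExpressionMatrix(atlas58, ("a", "b"), vals)
        corr = gene_correlation_matrix(em)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_pearson(self, rng):
        atlas = make_atlas(4, 0, 0, 0, seed=0)
        x = np.array([0.1, 0.4, 0.5, 0.9])
        y = np.array([0.2, 0.1, 0.7, 0.6])
        em = ExpressionMatrix(atlas, ("x", "y"), np.column_stack([x, y]))
        r_hand = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert gene_correlation_matrix(em).loc["x", "y"] == pytest.approx(r_hand)

    def test_constant_gene_flagged(self, atlas58):
        vals = np.column_stack(
            [np.full(58, 0.5), np.linspace(0, 1, 58)]
        )
        em = ExpressionMatrix(atlas58, ("const", "var"), vals)
        with pytest.warns(UserWarning, match="const"):
            corr = gene_correlation_matrix(em)
        assert np.isnan(corr.loc["const", "var"])


class TestEndToEnd:
    def test_noise_free_single_probe_passthrough(self, atlas58):
        # zero noise, one probe per gene, exact-centroid coverage: processed
        # matrix must be a monotone transform of the injected signal
        donors = simulate_donors(
            atlas58, 2, ["G1"], probes_per_gene=1, noise_sd=0.0,
            background_sd=0.0, coverage=1.0, n_far_samples=0, jitter_sd=0.0,
            seed=13,
        )
        matrix = process_donors(donors, atlas58)
        signal = donors[0].intensities[0]  # one sample per region, atlas order
        rho = stats.spearmanr(signal, matrix.values[:, 0]).statistic
        assert rho == pytest.approx(1.0)

    def test_full_pipeline_bounds_and_completeness(self, atlas58):
        donors = simulate_donors(
            atlas58, 4, ["G1", "G2", "G3"], probes_per_gene=3,
            weak_probe_fraction=0.2, seed=31,
        )
        matrix = process_donors(donors, atlas58)
        assert matrix.values.shape == (58, 3)
        assert np.isfinite(matrix.values).all()
        assert matrix.values.min() >= 0 and matrix.values.max() <= 1

    def test_filtering_never_grows_probe_set(self, atlas58):
        donors = simulate_donors(atlas58, 2, ["G1", "G2"], probes_per_gene=4,
                                 weak_probe_fraction=0.5, seed=8)
        retained, _ = filter_probes_by_intensity(donors)
        assert set(retained) <= set(donors[0].probe_ids)
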