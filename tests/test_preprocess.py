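"""Baseline correction, SNV, EEM flattening and fusion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oilspec as o
from oilspec.preprocess import moving_average_smooth
from oilspec.synth import EEM, Spectrum


def literal_baseline_transcription(I, span=20):
    """Independent, loop-based transcription of the derivative-cumsum
    baseline correction, written directly from its defining recipe."""
    I = np.asarray(I, dtype=float)
    n = len(I)
    d = [I[k + 1] - I[k] for k in range(n - 1)]
    if span % 2 == 0:
        span -= 1
    h = span // 2
    s = []
    for i in range(len(d)):
        hw = min(i, len(d) - 1 - i, h)
        s.append(sum(d[i - hw:i + hw + 1]) / (2 * hw + 1))
    c = np.cumsum(s)
    out = [I[0]] + [I[k] - c[k - 1] for k in range(1, n)]
    return np.array(out)


class TestBaselineCorrect:
    def test_constant_unchanged(self):
        x = np.full(100, 5.0)
        np.testing.assert_array_equal(o.baseline_correct(x), x)

    def test_linear_ramp_flattened_to_constant(self):
        k = np.arange(1, 101, dtype=float)
        np.testing.assert_allclose(o.baseline_correct(2.0 * k), 2.0, atol=1e-12)

    @given(st.floats(-50, 50), st.floats(-5, 5))
    def test_affine_input_maps_to_constant(self, intercept, slope):
        k = np.arange(150, dtype=float)
        out = o.baseline_correct(intercept + slope * k)
        np.testing.assert_allclose(out, intercept, atol=1e-9 * (1 + abs(intercept)))

    def test_matches_literal_transcription_on_random_vectors(self, rng):
        for _ in range(100):
            x = rng.normal(size=200)
            np.testing.assert_allclose(
                o.baseline_correct(x), literal_baseline_transcription(x), atol=1e-10
            )

    def test_rejects_short_and_nonfinite_input(self):
        with pytest.raises(ValueError):
            o.baseline_correct(np.arange(10.0))
        bad = np.ones(100)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            o.baseline_correct(bad)

    def test_smooth_even_span_forced_odd(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(
            moving_average_smooth(x, 20), moving_average_smooth(x, 19)
        )


class TestSNV:
    def test_three_point_example(self):
        np.testing.assert_allclose(o.snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=200))
    def test_output_standardised(self, values):
        x = np.asarray(values)
        if not x.std(ddof=1) > 1e-6:
            return
        out = o.snv(x)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=1) - 1.0) < 1e-9

    def test_idempotent(self, rng):
        for _ in range(10):
            x = rng.normal(size=100)
            np.testing.assert_allclose(o.snv(o.snv(x)), o.snv(x), atol=1e-9)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            o.snv(np.full(50, 3.0))


class TestEEMFlattening:
    def test_default_grid_flattens_to_936(self, grids):
        E = np.arange(26 * 36, dtype=float).reshape(26, 36)
        assert len(o.flatten_eem(E, grids["fluorescence"])) == 936

    def test_excitation_major_ordering(self, grids):
        E = np.zeros((26, 36))
        E[1, 0] = 7.0  # excitation index 2, emission index 1 (1-based)
        flat = o.flatten_eem(E, grids["fluorescence"])
        assert flat[36] == 7.0  # 1-based position 37

    def test_round_trip(self, grids, rng):
        E = rng.normal(size=(26, 36))
        g = grids["fluorescence"]
        np.testing.assert_array_equal(o.unflatten_eem(o.flatten_eem(E, g), g), E)

    def test_shape_mismatch_rejected(self, grids):
        with pytest.raises(ValueError):
            o.flatten_eem(np.zeros((36, 26)), grids["fluorescence"])


class TestPreprocessModality:
    def test_raman_standardised_after_chain(self, grids, rng):
        s = Spectrum(grids["raman"], rng.normal(size=1681) + 5.0)
        out = o.preprocess_modality(s)
        assert abs(out.intensities.mean()) < 1e-9
        assert abs(out.intensities.std(ddof=1) - 1.0) < 1e-9
        assert out.provenance == ["baseline_correct", "snv"]

    def test_fluorescence_left_raw(self, grids, rng):
        E = rng.uniform(size=(26, 36))
        s = EEM(grids["fluorescence"], E)
        out = o.preprocess_modality(s)
        np.testing.assert_array_equal(out.intensities, E.ravel())

    def test_constant_nir_rejected(self, grids):
        s = Spectrum(grids["nir"], np.full(134, 2.0))
        with pytest.raises(ValueError):
            o.preprocess_modality(s)


class TestFusion:
    def test_fused_length_and_offsets(self, grids, rng):
        fluo = rng.uniform(size=936)
        nir = o.preprocess_modality(Spectrum(grids["nir"], rng.normal(size=134) + 3))
        raman = o.preprocess_modality(Spectrum(grids["raman"], rng.normal(size=1681) + 3))
        fused = o.fuse(fluo, nir, raman)
        assert len(fused.intensities) == 2751
        assert fused.block_offsets == (0, 936, 1070)

    def test_blocks_preserved_bit_exactly(self, grids, rng):
        fluo = rng.uniform(size=936)
        nir = o.preprocess_modality(Spectrum(grids["nir"], rng.normal(size=134) + 3))
        raman = o.preprocess_modality(Spectrum(grids["raman"], rng.normal(size=1681) + 3))
        fused = o.fuse(fluo, nir, raman)
        np.testing.assert_array_equal(fused.block("fluorescence"), o.snv(fluo))
        np.testing.assert_array_equal(fused.block("nir"), nir.intensities)
        np.testing.assert_array_equal(fused.block("raman"), raman.intensities)
        assert abs(fused.block("fluorescence").mean()) < 1e-9

    def test_missing_block_rejected(self, grids, rng):
        nir = o.preprocess_modality(Spectrum(grids["nir"], rng.normal(size=134) + 3))
        with pytest.raises(ValueError):
            o.fuse(None, nir, nir)


class TestPreprocessDataset:
    def test_fused_matrix_shape(self, mexican_dataset):
        X, meta = o.preprocess_dataset(mexican_dataset, "fused")
        assert X.shape == (570, 2751)
        assert list(meta.columns) == [
            "sample_label", "preparation_index", "measurement_index",
        ]

    def test_unknown_modality_rejected(self, mexican_dataset):
        with pytest.raises(ValueError):
            o.preprocess_dataset(mexican_dataset, "uv")
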