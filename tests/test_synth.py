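"""Generator: designs, endmember library, mixing, noise, dataset counts."""

import numpy as np
import pytest

import oilspec as o
from oilspec.synth import CHIA_OILS, render_library


class TestDesigns:
    def test_mexican_counts_and_blends(self, mexican_design):
        labels = [r.label for r in mexican_design]
        assert len(mexican_design) == 38
        assert len(set(labels)) == 38
        assert sum(r.n_preparations for r in mexican_design) == 114
        assert all(r.n_preparations == 3 for r in mexican_design)
        by = {r.label: r for r in mexican_design}
        assert by["AS90"].blend.components == pytest.approx({"A": 0.90, "S": 0.10})
        assert by["RS50"].blend.components == pytest.approx({"R": 0.50, "S": 0.50})
        assert by["A100"].blend.components == {"A": 1.0}

    def test_kenyan_counts_and_preparations(self, kenyan_design):
        labels = [r.label for r in kenyan_design]
        assert len(kenyan_design) == 17
        assert len(set(labels)) == 17
        assert sum(r.n_preparations for r in kenyan_design) == 28
        by = {r.label: r for r in kenyan_design}
        assert by["US90"].n_preparations == 1
        assert by["US90"].blend.components == pytest.approx({"U": 0.9, "S": 0.1})
        assert by["VS50"].n_preparations == 2
        assert by["VS50"].blend.components == pytest.approx({"V": 0.5, "S": 0.5})
        singles = {lab for lab, r in by.items() if r.n_preparations == 1}
        assert singles == {"U100", "X100", "US90", "US50", "WS50", "XS90"}

    @pytest.mark.parametrize(
        "components",
        [{"A": 0.5, "S": 0.6}, {"A": -0.1, "S": 1.1}, {}],
    )
    def test_invalid_blends_rejected(self, components):
        with pytest.raises(ValueError):
            o.OilBlend(components)


class TestEndmemberLibrary:
    def test_deterministic_under_seed(self):
        assert o.make_endmember_library(1) == o.make_endmember_library(1)

    def test_pairwise_distinct_pure_spectra(self, library):
        rendered = {oil: o.render_fused_pure(sig) for oil, sig in library.items()}
        oils = sorted(rendered)
        for i, a in enumerate(oils):
            for b in oils[i + 1:]:
                u, v = rendered[a], rendered[b]
                cos = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                assert cos < 1 - 1e-3, (a, b, cos)

    def test_chia_oils_carry_chlorophyll_peak(self, library):
        for oil in CHIA_OILS:
            peaks = library[oil].fluoro_peaks
            assert any(
                abs(exc - 405) <= 10 and abs(emc - 670) <= 10 for exc, emc, _, _ in peaks
            ), oil

    def test_all_eleven_oils_present(self, library):
        assert set(library) == set("ABSRCUVWXYZ")


class TestMixing:
    def test_pure_blend_reproduces_endmember(self, library, grids):
        eem, nir, raman = o.synth_measurement(
            o.OilBlend({"A": 1.0}), library, grids, o.clean_noise()
        )
        rendered = o.render_endmember(library["A"], grids)
        np.testing.assert_array_equal(eem.intensities, rendered["fluorescence"])
        np.testing.assert_array_equal(nir.intensities, rendered["nir"])
        np.testing.assert_array_equal(raman.intensities, rendered["raman"])

    def test_linearity_in_mass_fraction(self, library, grids):
        eem, nir, raman = o.synth_measurement(
            o.OilBlend({"A": 0.5, "S": 0.5}), library, grids, o.clean_noise()
        )
        ra = o.render_endmember(library["A"], grids)
        rs = o.render_endmember(library["S"], grids)
        for spec, modality in ((eem, "fluorescence"), (nir, "nir"), (raman, "raman")):
            np.testing.assert_allclose(
                spec.intensities, 0.5 * ra[modality] + 0.5 * rs[modality], atol=1e-14
            )

    def test_unknown_oil_named_in_error(self, library):
        with pytest.raises(KeyError, match="Q"):
            o.synth_measurement(o.OilBlend({"Q": 1.0}), library)

    def test_additive_noise_mean_converges_to_noise_free(self, library, grids):
        """Monte-Carlo: the mean of many noisy draws approaches the clean
        spectrum within 4 standard errors at every grid point."""
        sd = 0.01
        noise = o.NoiseModel(additive_sd=sd, multiplicative_sd=0.0,
                             baseline_drift_sd=0.0, seed=7)
        blend = o.OilBlend({"A": 0.5, "S": 0.5})
        rendered = render_library({k: library[k] for k in "AS"}, grids)
        clean = 0.5 * rendered["A"]["nir"] + 0.5 * rendered["S"]["nir"]
        rng = np.random.default_rng(noise.seed)
        n = 10_000
        acc = np.zeros_like(clean)
        for _ in range(n):
            _, nir, _ = o.synth_measurement(blend, library, grids, noise, rng=rng,
                                            rendered=rendered)
            acc += nir.intensities
        tol = 4.0 * sd / np.sqrt(n)
        assert np.all(np.abs(acc / n - clean) < tol)


class TestGenerateDataset:
    def test_joint_design_yields_710_per_modality(self, library):
        ds = o.generate_dataset(o.build_design("both"), library,
                                noise=o.default_noise(1))
        for modality in ("fluorescence", "nir", "raman"):
            assert len(getattr(ds, modality)) == 710

    def test_mexican_dataset_has_570_per_modality(self, mexican_dataset):
        assert len(mexican_dataset.fluorescence) == 570
        assert len(mexican_dataset.nir) == 570
        assert len(mexican_dataset.raman) == 570

    def test_measurement_triples_unique_and_complete(self, mexican_dataset):
        for modality in ("fluorescence", "nir", "raman"):
            triples = [
                (s.sample_label, s.preparation_index, s.measurement_index)
                for s in getattr(mexican_dataset, modality)
            ]
            assert len(set(triples)) == len(triples) == 570

    def test_single_measurement_single_prep(self, library):
        row = o.DesignRow("A100", o.OilBlend({"A": 1.0}), 1)
        ds = o.generate_dataset([row], library, n_measurements=1)
        assert len(ds.fluorescence) == len(ds.nir) == len(ds.raman) == 1

    def test_bit_reproducible_under_seed(self, library):
        design = [o.DesignRow("AS90", o.OilBlend({"A": 0.9, "S": 0.1}), 2)]
        a = o.generate_dataset(design, library, noise=o.default_noise(9))
        b = o.generate_dataset(design, library, noise=o.default_noise(9))
        for s1, s2 in zip(a.raman + a.nir, b.raman + b.nir):
            np.testing.assert_array_equal(s1.intensities, s2.intensities)

    def test_empty_design_rejected(self, library):
        with pytest.raises(ValueError):
            o.generate_dataset([], library)
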