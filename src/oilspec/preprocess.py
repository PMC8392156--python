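"""Spectral preprocessing: baseline correction, SNV, EEM flattening, fusion.

NIR and Raman spectra are baseline-corrected by subtracting the cumulative
sum of the smoothed first differences,

    I_BC(k) = I(k) - cumsum[ smooth( diff I, 20 ) ],

followed by a standard normal variate (SNV) transformation

    I_SNV(k) = (I_BC(k) - mean(I_BC)) / sd(I_BC).

``smooth`` is a centered moving average whose even span is forced down to
the next odd value (20 -> 19) and whose endpoints are averaged over the
largest symmetric window that fits.  The first differences shorten the
vector by one; the cumulative baseline is applied with a one-point offset so
the output keeps the input length with the first point anchored
(``out[0] = I[0]``).  Because ``cumsum(diff I) = I(k) - I(0)``, the
correction acts as a high-pass filter: broad backgrounds are removed while
bands narrower than the smoothing span survive.

Fluorescence EEMs are left raw in single-modality analyses.  For low-level
fusion the flattened EEM is SNV-scaled (so its intensities are commensurate
with the preprocessed NIR/Raman blocks) and the NIR and Raman vectors are
appended, in that order, giving 936 + 134 + 1681 = 2751 points on the
default grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import AxisGrid
from .synth import EEM, SpectraDataset, Spectrum

#: Dataset-level modality names accepted by :func:`preprocess_dataset`.
DATASET_MODALITIES = ("fluo_raw", "fluo_snv", "nir", "raman", "fused")


def moving_average_smooth(x: np.ndarray, span: int = 20) -> np.ndarray:
    """Centered moving average with symmetric shrinking endpoint windows.

    Even spans are reduced to ``span - 1`` (a moving average needs an odd
    window to stay centered).  At position ``i`` the half-width is
    ``min(i, n-1-i, (span-1)//2)``, so the first/last points pass through
    unchanged and the window grows symmetrically towards the interior.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if span < 1:
        raise ValueError("span must be >= 1")
    if span % 2 == 0:
        span -= 1
    h = span // 2
    if n == 0 or h == 0:
        return x.copy()
    out = np.empty(n)
    if n >= span:
        kernel = np.full(span, 1.0 / span)
        out[h:n - h] = np.convolve(x, kernel, mode="valid")
    for i in range(min(h, n)):
        hw = min(i, n - 1 - i, h)
        out[i] = x[i - hw:i + hw + 1].mean()
    for i in range(max(n - h, 0), n):
        hw = min(i, n - 1 - i, h)
        out[i] = x[i - hw:i + hw + 1].mean()
    return out


def baseline_correct(intensities: np.ndarray, window: int = 20) -> np.ndarray:
    """Derivative-cumsum baseline correction (see module docstring).

    Maps any affine function of the index to a constant: the differences of
    an affine sequence are constant, their moving average is the same
    constant, and its cumulative sum reproduces the linear trend exactly.
    """
    I = np.asarray(intensities, dtype=float)
    if I.ndim != 1:
        raise ValueError("expected a 1-D intensity vector")
    if len(I) < window + 2:
        raise ValueError(f"need at least window + 2 = {window + 2} points, got {len(I)}")
    if not np.all(np.isfinite(I)):
        raise ValueError("intensities contain NaN/Inf")
    baseline = np.cumsum(moving_average_smooth(np.diff(I), window))
    out = I.copy()
    out[1:] -= baseline
    return out


def snv(intensities: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Uses the sample (n-1) standard deviation.  Raises on a constant
    spectrum, for which the transformation is undefined.
    """
    I = np.asarray(intensities, dtype=float)
    sd = I.std(ddof=1)
    if not sd > 0:
        raise ValueError("degenerate spectrum: standard deviation is zero")
    return (I - I.mean()) / sd


def flatten_eem(matrix: np.ndarray, grid: AxisGrid) -> np.ndarray:
    """Flatten an EEM excitation-major (ascending excitation outer loop,
    ascending emission inner loop)."""
    E = np.asarray(matrix, dtype=float)
    if grid.modality != "fluorescence":
        raise ValueError("grid is not a fluorescence grid")
    if E.shape != grid.shape:
        raise ValueError(f"EEM shape {E.shape} does not match grid {grid.shape}")
    return E.reshape(-1)


def unflatten_eem(vector: np.ndarray, grid: AxisGrid) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    if v.shape != (grid.n_points,):
        raise ValueError(f"vector length {v.shape} does not match grid {grid.n_points}")
    return v.reshape(grid.shape)


@dataclass
class PreprocessedSpectrum:
    """Result of per-modality preprocessing, with provenance."""

    intensities: np.ndarray
    provenance: list[str] = field(default_factory=list)
    mean_used: float | None = None
    sd_used: float | None = None


def preprocess_modality(spectrum: Spectrum, snv_fluorescence: bool = False
                        ) -> PreprocessedSpectrum:
    """Apply the modality's preprocessing chain to one spectrum.

    NIR/Raman: baseline correction then SNV.  Fluorescence: flattened raw
    intensities (optionally SNV-scaled when ``snv_fluorescence`` is set,
    mirroring the "with preprocessing" variant of the fluorescence-only
    analyses).
    """
    modality = spectrum.grid.modality
    if modality == "fluorescence":
        flat = flatten_eem(spectrum.intensities, spectrum.grid)
        if snv_fluorescence:
            return PreprocessedSpectrum(snv(flat), ["flatten", "snv"],
                                        float(flat.mean()), float(flat.std(ddof=1)))
        return PreprocessedSpectrum(flat, ["flatten"])
    bc = baseline_correct(spectrum.intensities)
    return PreprocessedSpectrum(snv(bc), ["baseline_correct", "snv"],
                                float(bc.mean()), float(bc.std(ddof=1)))


@dataclass
class FusedSpectrum:
    """Concatenated (fluorescence, NIR, Raman) feature vector."""

    intensities: np.ndarray
    block_offsets: tuple[int, int, int]

    def block(self, modality: str) -> np.ndarray:
        order = ("fluorescence", "nir", "raman")
        i = order.index(modality)
        start = self.block_offsets[i]
        end = self.block_offsets[i + 1] if i + 1 < 3 else len(self.intensities)
        return self.intensities[start:end]


def fuse(fluo: np.ndarray, nir: PreprocessedSpectrum, raman: PreprocessedSpectrum
         ) -> FusedSpectrum:
    """Low-level fusion: SNV-scale the flattened raw EEM, then append the
    preprocessed NIR and Raman blocks (fixed block order)."""
    if fluo is None or nir is None or raman is None:
        raise ValueError("all three modality blocks are required for fusion")
    fluo_scaled = snv(np.asarray(fluo, dtype=float))
    blocks = [fluo_scaled, np.asarray(nir.intensities), np.asarray(raman.intensities)]
    offsets = (0, len(blocks[0]), len(blocks[0]) + len(blocks[1]))
    return FusedSpectrum(np.concatenate(blocks), offsets)


def preprocess_dataset(dataset: SpectraDataset, modality: str
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Preprocess a whole dataset into a feature matrix.

    ``modality`` is one of ``fluo_raw`` (raw flattened EEMs), ``fluo_snv``
    (SNV-scaled EEMs), ``nir``, ``raman`` (baseline-corrected + SNV) or
    ``fused`` (2751-point fused vectors).  Returns the matrix and a metadata
    frame (sample_label, preparation_index, measurement_index) aligned row
    by row.
    """
    if modality not in DATASET_MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {DATASET_MODALITIES}")

    meta = pd.DataFrame(
        {
            "sample_label": [s.sample_label for s in dataset.fluorescence],
            "preparation_index": [s.preparation_index for s in dataset.fluorescence],
            "measurement_index": [s.measurement_index for s in dataset.fluorescence],
        }
    )
    # generate_dataset appends the three modalities in lockstep; verify.
    for mod_list in (dataset.nir, dataset.raman):
        if len(mod_list) != len(dataset.fluorescence):
            raise ValueError("modalities are not aligned")

    rows: list[np.ndarray] = []
    if modality in ("fluo_raw", "fluo_snv"):
        for s in dataset.fluorescence:
            rows.append(
                preprocess_modality(s, snv_fluorescence=(modality == "fluo_snv")).intensities
            )
    elif modality in ("nir", "raman"):
        for s in getattr(dataset, modality):
            rows.append(preprocess_modality(s).intensities)
    else:
        for e, n, r in zip(dataset.fluorescence, dataset.nir, dataset.raman):
            if (e.sample_label, e.preparation_index, e.measurement_index) != (
                n.sample_label, n.preparation_index, n.measurement_index,
            ) or (e.sample_label, e.preparation_index, e.measurement_index) != (
                r.sample_label, r.preparation_index, r.measurement_index,
            ):
                raise ValueError("measurement triples are not aligned across modalities")
            fused = fuse(
                flatten_eem(e.intensities, e.grid),
                preprocess_modality(n),
                preprocess_modality(r),
            )
            rows.append(fused.intensities)
    return np.vstack(rows), meta
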