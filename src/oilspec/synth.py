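"""Synthetic multi-modal oil spectra.

This module generates desk-scale stand-ins for spectroscopic measurements of
chia oil and its adulterations: blend designs, parametric pure-oil
("endmember") signatures, and noisy mixture measurements on the default
instrument grids.

Study designs
-------------
Two designs are built in:

* the *Mexican* design: two market chia oils (A, B) adulterated with
  sunflower (S), rapeseed (R) and corn (C) oil at 1/2/5/10/50 mass %, plus the
  five native oils and nine additional 50:50 combinations — 38 labelled
  blends, each prepared in triplicate (114 prepared samples);
* the *Kenyan* design: six chia oils (U-Z) from different growth sites
  adulterated with sunflower oil at 10/50 mass % — 17 labelled blends, six of
  which were prepared once and the rest twice (28 prepared samples).

Every prepared sample is measured 5 times on each of the three instruments,
so the joint design yields 710 spectra per modality.

Spectral model
--------------
Pure-oil signatures are sums of Gaussian bands plus a low-order polynomial
baseline per modality (for fluorescence, 2-D Gaussians on the
excitation x emission plane).  Every chia oil carries the chlorophyll
fluorescence feature near excitation 405 nm / emission 670 nm; the refined
adulterant oils are nearly chlorophyll-free but fluoresce more strongly in
the tocopherol/oxidation-product regions.  Mixture spectra are linear in mass
fraction (Beer-Lambert-style, no interaction terms).  Measurement noise is
applied per spectrum in fixed order: multiplicative gain, smooth baseline
drift (NIR/Raman only), additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grids import AxisGrid, default_grids

CHIA_OILS = ("A", "B", "U", "V", "W", "X", "Y", "Z")
ADULTERANT_OILS = ("S", "R", "C")
ALL_OILS = ("A", "B", "S", "R", "C", "U", "V", "W", "X", "Y", "Z")


# ---------------------------------------------------------------------------
# blends and designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OilBlend:
    """Mass fractions of named oils; fractions must sum to one."""

    components: dict[str, float]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("blend must contain at least one oil")
        for oil, frac in self.components.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction of oil {oil!r} outside [0, 1]: {frac}")
        total = math.fsum(self.components.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"blend fractions sum to {total!r}, not 1")

    def fraction(self, oil_id: str) -> float:
        return self.components.get(oil_id, 0.0)


@dataclass(frozen=True)
class DesignRow:
    """One labelled blend of a study design."""

    label: str
    blend: OilBlend
    n_preparations: int

    def __post_init__(self) -> None:
        if self.n_preparations < 1:
            raise ValueError("n_preparations must be positive")


def _binary_blend(major: str, minor: str, major_pct: int) -> OilBlend:
    frac = major_pct / 100.0
    return OilBlend({major: frac, minor: 1.0 - frac})


def build_design_mexican() -> list[DesignRow]:
    """The 38-row Mexican design: 2 chia oils x 3 adulterants x 4 levels,
    5 native oils and 9 additional 50:50 combinations, all in triplicate."""
    rows: list[DesignRow] = []
    for oil in ("A", "B", "S", "R", "C"):
        rows.append(DesignRow(f"{oil}100", OilBlend({oil: 1.0}), 3))
    for chia in ("A", "B"):
        for adult in ("S", "R", "C"):
            for pct in (90, 95, 98, 99):
                rows.append(
                    DesignRow(f"{chia}{adult}{pct}", _binary_blend(chia, adult, pct), 3)
                )
    for major, minor in (
        ("R", "S"), ("R", "C"), ("S", "C"),
        ("A", "S"), ("A", "R"), ("A", "C"),
        ("B", "S"), ("B", "R"), ("B", "C"),
    ):
        rows.append(DesignRow(f"{major}{minor}50", _binary_blend(major, minor, 50), 3))
    return rows


# Kenyan rows prepared only once (limited sample volume); all others twice.
_KENYAN_SINGLE = frozenset({"U100", "X100", "US90", "US50", "WS50", "XS90"})


def build_design_kenyan() -> list[DesignRow]:
    """The 17-row Kenyan design: six chia oils U-Z adulterated with sunflower
    at 10 and 50 mass % (28 prepared samples in total)."""
    rows: list[DesignRow] = []
    for oil in ("U", "V", "W", "X", "Y", "Z"):
        label = f"{oil}100"
        rows.append(DesignRow(label, OilBlend({oil: 1.0}), 1 if label in _KENYAN_SINGLE else 2))
    pairs = [
        ("U", 90), ("U", 50), ("V", 90), ("V", 50), ("W", 50),
        ("X", 90), ("X", 50), ("Y", 90), ("Y", 50), ("Z", 90), ("Z", 50),
    ]
    for oil, pct in pairs:
        label = f"{oil}S{pct}"
        rows.append(
            DesignRow(label, _binary_blend(oil, "S", pct), 1 if label in _KENYAN_SINGLE else 2)
        )
    return rows


def build_design(name: str) -> list[DesignRow]:
    if name == "mexican":
        return build_design_mexican()
    if name == "kenyan":
        return build_design_kenyan()
    if name == "both":
        return build_design_mexican() + build_design_kenyan()
    raise ValueError(f"unknown design {name!r}")


# ---------------------------------------------------------------------------
# endmember signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndmemberSignature:
    """Parametric pure-oil spectrum: Gaussian bands + polynomial baselines.

    ``fluoro_peaks`` entries are ``(excitation_center, emission_center,
    width, amplitude)``; ``nir_bands``/``raman_bands`` entries are
    ``(center, width, amplitude)``.  ``baselines`` maps modality to low-order
    polynomial coefficients evaluated on the axis normalised to [0, 1].
    """

    oil_id: str
    fluoro_peaks: tuple[tuple[float, float, float, float], ...]
    nir_bands: tuple[tuple[float, float, float], ...]
    raman_bands: tuple[tuple[float, float, float], ...]
    baselines: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for peaks in (self.fluoro_peaks,):
            if any(p[3] < 0 for p in peaks):
                raise ValueError("fluorescence amplitudes must be >= 0")
        for bands in (self.nir_bands, self.raman_bands):
            if any(b[2] < 0 for b in bands):
                raise ValueError("band amplitudes must be >= 0")


# Band placements follow the usual vegetable-oil assignments: fluorescence
# from tocopherols (~ex 300/em 390), oxidation products (~ex 370/em 450),
# riboflavin (~em 524) and chlorophyll (ex 405/em 670); NIR C-H overtone and
# combination bands (1210/1390/1725/1760/2140/2310 nm); Raman C-C, =C-H,
# CH2 and C=C modes (1080-1747, 2855-3010 cm^-1).  Relative amplitudes of
# the unsaturation-sensitive bands (Raman 1265/1655/3010, NIR 2140) separate
# the highly polyunsaturated chia oils from the adulterants.
_CHIA_TEMPLATE = {
    "fluoro": [
        (405.0, 670.0, 28.0, 1.00),   # chlorophyll
        (300.0, 390.0, 30.0, 0.35),   # tocopherols
        (370.0, 450.0, 35.0, 0.18),   # oxidation products (low in fresh chia)
        (450.0, 524.0, 30.0, 0.12),   # riboflavin
    ],
    "nir": [
        (930.0, 35.0, 0.18), (1210.0, 45.0, 0.42), (1390.0, 40.0, 0.30),
        (1725.0, 38.0, 0.85), (1760.0, 30.0, 0.55), (2140.0, 45.0, 0.62),
        (2310.0, 40.0, 0.75), (2350.0, 35.0, 0.50),
    ],
    "raman": [
        (1080.0, 14.0, 0.35), (1265.0, 12.0, 0.55), (1302.0, 12.0, 0.60),
        (1442.0, 14.0, 0.85), (1655.0, 13.0, 0.92), (1747.0, 12.0, 0.30),
        (2855.0, 20.0, 0.95), (2900.0, 22.0, 0.80), (3010.0, 16.0, 0.65),
    ],
}

_ADULTERANT_TEMPLATES = {
    # refined oils: chlorophyll almost absent, stronger tocopherol /
    # oxidation-product fluorescence, lower polyunsaturation bands
    "S": {
        "fluoro": [
            (405.0, 670.0, 28.0, 0.04),
            (300.0, 390.0, 30.0, 1.10),
            (370.0, 450.0, 35.0, 0.55),
            (450.0, 524.0, 30.0, 0.50),
        ],
        "nir_scale": {2140.0: 0.40, 2310.0: 0.68, 1725.0: 0.90},
        "raman_scale": {1265.0: 0.38, 1655.0: 0.68, 3010.0: 0.34},
    },
    "R": {
        "fluoro": [
            (405.0, 670.0, 28.0, 0.08),
            (300.0, 390.0, 30.0, 0.72),
            (370.0, 450.0, 35.0, 0.80),
            (450.0, 524.0, 30.0, 0.35),
        ],
        "nir_scale": {2140.0: 0.34, 2310.0: 0.80, 1390.0: 0.36},
        "raman_scale": {1265.0: 0.30, 1655.0: 0.58, 3010.0: 0.26, 1302.0: 0.70},
    },
    "C": {
        "fluoro": [
            (405.0, 670.0, 28.0, 0.05),
            (320.0, 410.0, 32.0, 0.95),
            (370.0, 450.0, 35.0, 0.45),
            (460.0, 530.0, 30.0, 0.55),
        ],
        "nir_scale": {2140.0: 0.46, 1210.0: 0.50, 1760.0: 0.42},
        "raman_scale": {1265.0: 0.44, 1655.0: 0.74, 3010.0: 0.42, 1080.0: 0.45},
    },
}

_BASELINES = {
    "fluorescence": (0.02,),
    "nir": (0.15, 0.10, -0.05),
    "raman": (0.80, -0.55, 0.20),
}

# Raman fluorescence-background level scales with pigment content and
# differs markedly between oils; NIR scatter baselines differ mildly.
_RAMAN_BASE_SCALE = {
    "A": 1.00, "B": 0.55, "S": 1.45, "R": 0.85, "C": 1.20,
    "U": 0.40, "V": 0.70, "W": 1.00, "X": 1.30, "Y": 1.60, "Z": 1.90,
}


def _oil_baselines(oil_id: str) -> dict[str, tuple[float, ...]]:
    s = _RAMAN_BASE_SCALE.get(oil_id, 1.0)
    out = dict(_BASELINES)
    out["raman"] = tuple(c * s for c in _BASELINES["raman"])
    out["nir"] = tuple(c * (0.8 + 0.4 * (s % 1.0)) for c in _BASELINES["nir"])
    return out


def _jitter_bands(bands, rng: np.random.Generator, amp_sd: float, center_sd: float):
    out = []
    for c, w, a in bands:
        out.append(
            (
                c + center_sd * float(rng.standard_normal()),
                w,
                a * max(0.0, 1.0 + amp_sd * float(rng.standard_normal())),
            )
        )
    return tuple(out)


def _jitter_fluoro(peaks, rng: np.random.Generator, amp_sd: float, center_sd: float,
                   max_shift: float = 6.0):
    out = []
    for exc, emc, w, a in peaks:
        dex = float(np.clip(center_sd * rng.standard_normal(), -max_shift, max_shift))
        dem = float(np.clip(center_sd * rng.standard_normal(), -max_shift, max_shift))
        out.append((exc + dex, emc + dem,
                    w, a * max(0.0, 1.0 + amp_sd * float(rng.standard_normal()))))
    return tuple(out)


def make_endmember_library(seed: int = 0) -> dict[str, EndmemberSignature]:
    """Build signatures for all 11 oils (A, B, S, R, C, U-Z).

    A and B are two distinct Mexican chia signatures; U-Z share the chia
    family with per-oil perturbations (different growth sites); S, R, C are
    the refined adulterant oils.  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    lib: dict[str, EndmemberSignature] = {}

    def chia_like(oil_id: str, amp_sd: float, center_sd: float) -> EndmemberSignature:
        return EndmemberSignature(
            oil_id=oil_id,
            fluoro_peaks=_jitter_fluoro(_CHIA_TEMPLATE["fluoro"], rng, amp_sd, center_sd),
            nir_bands=_jitter_bands(_CHIA_TEMPLATE["nir"], rng, amp_sd, center_sd),
            raman_bands=_jitter_bands(_CHIA_TEMPLATE["raman"], rng, amp_sd, center_sd),
            baselines=_oil_baselines(oil_id),
        )

    # Mexican chia oils: two clearly distinct members of the family.
    lib["A"] = chia_like("A", amp_sd=0.03, center_sd=0.5)
    b = chia_like("B", amp_sd=0.03, center_sd=0.5)
    b_fluoro = tuple(
        (exc, emc, w, a * f)
        for (exc, emc, w, a), f in zip(b.fluoro_peaks, (1.25, 0.80, 1.30, 0.90))
    )
    b_raman = tuple(
        (c, w, a * (1.08 if c in (1655.0, 3010.0) else 1.0)) for (c, w, a) in b.raman_bands
    )
    b_nir = tuple(
        (c, w, a * (0.88 if c == 2140.0 else 1.0)) for (c, w, a) in b.nir_bands
    )
    lib["B"] = EndmemberSignature("B", b_fluoro, b_nir, b_raman, _oil_baselines("B"))

    for oil in ADULTERANT_OILS:
        tpl = _ADULTERANT_TEMPLATES[oil]
        nir = tuple(
            (c, w, a * tpl["nir_scale"].get(c, 1.0)) for (c, w, a) in _CHIA_TEMPLATE["nir"]
        )
        raman = tuple(
            (c, w, a * tpl["raman_scale"].get(c, 1.0)) for (c, w, a) in _CHIA_TEMPLATE["raman"]
        )
        lib[oil] = EndmemberSignature(
            oil,
            _jitter_fluoro(tuple(tpl["fluoro"]), rng, 0.03, 0.5),
            _jitter_bands(nir, rng, 0.03, 0.5),
            _jitter_bands(raman, rng, 0.03, 0.5),
            _oil_baselines(oil),
        )

    # Kenyan chia oils: same family, larger site-to-site perturbations.  A
    # deterministic per-site modulation of the pigment and unsaturation bands
    # (growth-site composition differences) keeps the signatures pairwise
    # distinct for every seed; the seeded jitter adds batch idiosyncrasy.
    for i, oil in enumerate(("U", "V", "W", "X", "Y", "Z")):
        base = chia_like(oil, amp_sd=0.10, center_sd=2.5)
        ffac = (0.70 + 0.12 * i, 1.30 - 0.10 * i, 0.80 + 0.15 * i, 1.25 - 0.09 * i)
        fluoro = tuple(
            (exc, emc, w, a * f) for (exc, emc, w, a), f in zip(base.fluoro_peaks, ffac)
        )
        # site-specific minor pigment/phenolic features at per-site positions
        fluoro = fluoro + ((440.0 + 12.0 * i, 540.0 + 14.0 * i, 25.0, 0.20),)
        rscale = {1655.0: 0.85 + 0.07 * i, 3010.0: 1.20 - 0.09 * i,
                  1265.0: 0.80 + 0.08 * i}
        raman = tuple((c, w, a * rscale.get(c, 1.0)) for (c, w, a) in base.raman_bands)
        raman = raman + ((700.0 + 150.0 * i, 15.0, 0.25),)
        nscale = {2140.0: 0.85 + 0.06 * i, 1725.0: 1.12 - 0.05 * i}
        nir = tuple((c, w, a * nscale.get(c, 1.0)) for (c, w, a) in base.nir_bands)
        nir = nir + ((1000.0 + 120.0 * i, 30.0, 0.15),)
        lib[oil] = EndmemberSignature(oil, fluoro, nir, raman, _oil_baselines(oil))

    return lib


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _polybase(coeffs: tuple[float, ...], x: np.ndarray) -> np.ndarray:
    xn = (x - x[0]) / (x[-1] - x[0])
    return np.polynomial.polynomial.polyval(xn, np.asarray(coeffs))


def render_endmember(sig: EndmemberSignature, grids: dict[str, AxisGrid] | None = None
                     ) -> dict[str, np.ndarray]:
    """Noise-free pure-oil intensities on each grid.

    Returns ``{"fluorescence": (n_ex, n_em) matrix, "nir": vector,
    "raman": vector}``.
    """
    grids = grids or default_grids()
    fgrid = grids["fluorescence"]
    ex = np.asarray(fgrid.excitation)[:, None]
    em = np.asarray(fgrid.emission)[None, :]
    eem = np.full(fgrid.shape, float(sig.baselines.get("fluorescence", (0.0,))[0]))
    for exc, emc, w, a in sig.fluoro_peaks:
        eem += a * np.exp(-((ex - exc) ** 2 + (em - emc) ** 2) / (2.0 * w * w))

    out = {"fluorescence": eem}
    for modality, bands in (("nir", sig.nir_bands), ("raman", sig.raman_bands)):
        x = np.asarray(grids[modality].values)
        v = _polybase(sig.baselines.get(modality, (0.0,)), x)
        for c, w, a in bands:
            v = v + a * np.exp(-((x - c) ** 2) / (2.0 * w * w))
        out[modality] = v
    return out


def render_library(library: dict[str, EndmemberSignature],
                   grids: dict[str, AxisGrid] | None = None
                   ) -> dict[str, dict[str, np.ndarray]]:
    grids = grids or default_grids()
    return {oil: render_endmember(sig, grids) for oil, sig in library.items()}


def render_fused_pure(sig: EndmemberSignature, grids: dict[str, AxisGrid] | None = None
                      ) -> np.ndarray:
    """Concatenated (fluorescence, NIR, Raman) noise-free pure spectrum."""
    r = render_endmember(sig, grids)
    return np.concatenate([r["fluorescence"].ravel(), r["nir"], r["raman"]])


# ---------------------------------------------------------------------------
# noise model and measurement synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Instrument/preparation variability on unit-scale intensities.

    ``multiplicative_sd`` scales the whole spectrum by ``1 + N(0, sd)`` (gain
    / path-length variation), ``baseline_drift_sd`` adds a smooth random
    cubic to NIR and Raman spectra, ``additive_sd`` adds i.i.d. Gaussian
    noise at every point, in that order.
    """

    additive_sd: float = 0.005
    multiplicative_sd: float = 0.01
    baseline_drift_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_sd", "baseline_drift_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


def default_noise(seed: int = 0) -> NoiseModel:
    return NoiseModel(seed=seed)


def clean_noise(seed: int = 0) -> NoiseModel:
    """Noise-free profile (useful for exactness checks)."""
    return NoiseModel(additive_sd=0.0, multiplicative_sd=0.0, baseline_drift_sd=0.0, seed=seed)


NOISE_PROFILES = {"default": default_noise, "clean": clean_noise}


@dataclass
class Spectrum:
    """One measured spectrum (NIR or Raman) with its sample metadata."""

    grid: AxisGrid
    intensities: np.ndarray
    sample_label: str = ""
    preparation_index: int = 1
    measurement_index: int = 1

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.grid.shape:
            raise ValueError("intensity shape does not match grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain NaN/Inf")


@dataclass
class EEM(Spectrum):
    """Excitation x emission fluorescence intensity matrix."""


def _apply_noise(values: np.ndarray, modality: str, noise: NoiseModel,
                 rng: np.random.Generator, axis: np.ndarray | None) -> np.ndarray:
    out = values * (1.0 + noise.multiplicative_sd * rng.standard_normal())
    if modality in ("nir", "raman") and axis is not None:
        xn = (axis - axis[0]) / (axis[-1] - axis[0])
        coeffs = noise.baseline_drift_sd * rng.standard_normal(4)
        out = out + np.polynomial.polynomial.polyval(xn, coeffs)
    out = out + noise.additive_sd * rng.standard_normal(values.shape)
    return out


def synth_measurement(
    blend: OilBlend,
    library: dict[str, EndmemberSignature],
    grids: dict[str, AxisGrid] | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    rendered: dict[str, dict[str, np.ndarray]] | None = None,
    sample_label: str = "",
    preparation_index: int = 1,
    measurement_index: int = 1,
) -> tuple[EEM, Spectrum, Spectrum]:
    """Simulate one measurement triple (EEM, NIR, Raman) for a blend.

    The noise-free intensity at every grid point is the mass-fraction
    weighted sum of the pure-oil intensities; noise is then applied per
    modality in the order fluorescence, NIR, Raman (one RNG stream).
    """
    grids = grids or default_grids()
    noise = noise or default_noise()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    unknown = [oil for oil in blend.components if oil not in library]
    if unknown:
        raise KeyError(f"blend references unknown oil(s): {', '.join(sorted(unknown))}")
    rendered = rendered or render_library(
        {oil: library[oil] for oil in blend.components}, grids
    )

    mixed = {}
    for modality in ("fluorescence", "nir", "raman"):
        acc = None
        for oil, frac in blend.components.items():
            term = frac * rendered[oil][modality]
            acc = term if acc is None else acc + term
        mixed[modality] = acc

    meta = dict(
        sample_label=sample_label,
        preparation_index=preparation_index,
        measurement_index=measurement_index,
    )
    eem = EEM(
        grids["fluorescence"],
        _apply_noise(mixed["fluorescence"], "fluorescence", noise, rng, None),
        **meta,
    )
    nir = Spectrum(
        grids["nir"],
        _apply_noise(mixed["nir"], "nir", noise, rng, np.asarray(grids["nir"].values)),
        **meta,
    )
    raman = Spectrum(
        grids["raman"],
        _apply_noise(mixed["raman"], "raman", noise, rng, np.asarray(grids["raman"].values)),
        **meta,
    )
    return eem, nir, raman


@dataclass
class SpectraDataset:
    """All measured spectra of one study design, per modality."""

    fluorescence: list[EEM]
    nir: list[Spectrum]
    raman: list[Spectrum]
    design: list[DesignRow]

    def n_spectra(self, modality: str) -> int:
        return len(getattr(self, modality if modality != "fluorescence" else "fluorescence"))

    @property
    def labels(self) -> set[str]:
        return {row.label for row in self.design}

    def blend_of(self, label: str) -> OilBlend:
        for row in self.design:
            if row.label == label:
                return row.blend
        raise KeyError(f"no design row labelled {label!r}")


def generate_dataset(
    design: list[DesignRow],
    library: dict[str, EndmemberSignature] | None = None,
    grids: dict[str, AxisGrid] | None = None,
    noise: NoiseModel | None = None,
    n_measurements: int = 5,
) -> SpectraDataset:
    """Simulate every (blend, preparation, measurement) triple of a design.

    One RNG stream seeded from ``noise.seed`` is consumed in fixed iteration
    order, so the full dataset is bit-reproducible for a fixed seed.
    """
    if not design:
        raise ValueError("design is empty")
    if n_measurements < 1:
        raise ValueError("n_measurements must be >= 1")
    labels = [row.label for row in design]
    if len(set(labels)) != len(labels):
        raise ValueError("design labels are not unique")
    library = library or make_endmember_library()
    grids = grids or default_grids()
    noise = noise or default_noise()
    rng = np.random.default_rng(noise.seed)
    rendered = render_library(library, grids)

    fluo: list[EEM] = []
    nir: list[Spectrum] = []
    raman: list[Spectrum] = []
    for row in design:
        for prep in range(1, row.n_preparations + 1):
            for meas in range(1, n_measurements + 1):
                e, n, r = synth_measurement(
                    row.blend, library, grids, noise, rng=rng, rendered=rendered,
                    sample_label=row.label, preparation_index=prep,
                    measurement_index=meas,
                )
                fluo.append(e)
                nir.append(n)
                raman.append(r)
    return SpectraDataset(fluo, nir, raman, list(design))
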