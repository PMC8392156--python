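"""Instrument axis grids for the three spectroscopic modalities.

The pipeline works on three fixed measurement grids:

* fluorescence excitation-emission matrices (EEM): excitation 300-550 nm and
  emission 350-700 nm, both in 10 nm steps, i.e. 26 x 36 = 936 wavelength
  combinations per spectrum;
* near infrared (NIR): 800-2795 nm at 15 nm resolution (134 points);
* Raman: 350-3200 cm^-1 sampled at 1681 evenly spaced points.

Fusing one spectrum per modality therefore yields 936 + 134 + 1681 = 2751
feature points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODALITIES = ("fluorescence", "nir", "raman")

#: Fused feature-vector length on the default grids.
FUSED_LENGTH = 2751


def _strictly_increasing(v: np.ndarray) -> bool:
    return bool(np.all(np.diff(v) > 0))


@dataclass(frozen=True)
class AxisGrid:
    """Measurement axis for one modality.

    For ``nir``/``raman`` the axis is ``values`` (nm resp. cm^-1).  For
    ``fluorescence`` the axis is the full cross product of ``excitation`` and
    ``emission`` wavelengths (nm); intensities are stored as an
    ``(n_excitation, n_emission)`` matrix and flattened excitation-major.
    """

    modality: str
    values: np.ndarray | None = None
    excitation: np.ndarray | None = None
    emission: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "fluorescence":
            if self.excitation is None or self.emission is None:
                raise ValueError("fluorescence grid needs excitation and emission axes")
            for name, ax in (("excitation", self.excitation), ("emission", self.emission)):
                if not _strictly_increasing(np.asarray(ax)):
                    raise ValueError(f"{name} axis must be strictly increasing")
        else:
            if self.values is None:
                raise ValueError(f"{self.modality} grid needs axis values")
            if not _strictly_increasing(np.asarray(self.values)):
                raise ValueError("axis values must be strictly increasing")

    @property
    def n_points(self) -> int:
        if self.modality == "fluorescence":
            return len(self.excitation) * len(self.emission)
        return len(self.values)

    @property
    def shape(self) -> tuple[int, ...]:
        if self.modality == "fluorescence":
            return (len(self.excitation), len(self.emission))
        return (len(self.values),)

    def column_names(self) -> list[str]:
        """Column headers for the wide-CSV on-disk form."""
        if self.modality == "fluorescence":
            return [
                f"ex{int(ex)}_em{int(em)}"
                for ex in self.excitation
                for em in self.emission
            ]
        return [f"{v:g}" for v in self.values]


def default_fluorescence_grid() -> AxisGrid:
    return AxisGrid(
        "fluorescence",
        excitation=np.arange(300.0, 551.0, 10.0),
        emission=np.arange(350.0, 701.0, 10.0),
    )


def default_nir_grid() -> AxisGrid:
    # 800 .. 2795 nm at the instrument's 15 nm resolution -> 134 points
    return AxisGrid("nir", values=np.arange(800.0, 2800.0, 15.0))


def default_raman_grid() -> AxisGrid:
    return AxisGrid("raman", values=np.linspace(350.0, 3200.0, 1681))


def default_grids() -> dict[str, AxisGrid]:
    """The three default instrument grids keyed by modality."""
    return {
        "fluorescence": default_fluorescence_grid(),
        "nir": default_nir_grid(),
        "raman": default_raman_grid(),
    }
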