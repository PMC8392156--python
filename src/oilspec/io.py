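"""On-disk formats: wide spectra CSVs with metadata/design sidecars.

A dataset directory holds one wide CSV per modality
(``spectra_fluorescence.csv``, ``spectra_nir.csv``, ``spectra_raman.csv``;
header row = axis values, fluorescence columns named ``ex<nm>_em<nm>``), a
``metadata.csv`` aligned row by row (sample_label, blend as a JSON string,
preparation_index, measurement_index) and a ``design.csv`` (label, blend
JSON, n_preparations).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import AxisGrid, default_grids
from .synth import EEM, DesignRow, OilBlend, SpectraDataset, Spectrum

SPECTRA_FILES = {
    "fluorescence": "spectra_fluorescence.csv",
    "nir": "spectra_nir.csv",
    "raman": "spectra_raman.csv",
}


def write_dataset(dataset: SpectraDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for modality, fname in SPECTRA_FILES.items():
        spectra = getattr(dataset, modality)
        grid = spectra[0].grid
        rows = [s.intensities.ravel() for s in spectra]
        df = pd.DataFrame(np.vstack(rows), columns=grid.column_names())
        path = outdir / fname
        df.to_csv(path, index=False)
        written[modality] = path

    meta = pd.DataFrame(
        {
            "sample_label": [s.sample_label for s in dataset.fluorescence],
            "blend": [
                json.dumps(dataset.blend_of(s.sample_label).components, sort_keys=True)
                for s in dataset.fluorescence
            ],
            "preparation_index": [s.preparation_index for s in dataset.fluorescence],
            "measurement_index": [s.measurement_index for s in dataset.fluorescence],
        }
    )
    meta_path = outdir / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    written["metadata"] = meta_path

    design = pd.DataFrame(
        {
            "label": [r.label for r in dataset.design],
            "blend": [json.dumps(r.blend.components, sort_keys=True) for r in dataset.design],
            "n_preparations": [r.n_preparations for r in dataset.design],
        }
    )
    design_path = outdir / "design.csv"
    design.to_csv(design_path, index=False)
    written["design"] = design_path
    return written


def _grid_from_columns(modality: str, columns: list[str]) -> AxisGrid:
    if modality == "fluorescence":
        ex = sorted({int(c.split("_")[0][2:]) for c in columns})
        em = sorted({int(c.split("_")[1][2:]) for c in columns})
        return AxisGrid("fluorescence", excitation=np.array(ex, dtype=float),
                        emission=np.array(em, dtype=float))
    return AxisGrid(modality, values=np.array([float(c) for c in columns]))


def read_dataset(indir: str | Path) -> SpectraDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    design_df = pd.read_csv(indir / "design.csv")
    design = [
        DesignRow(row["label"], OilBlend(json.loads(row["blend"])), int(row["n_preparations"]))
        for _, row in design_df.iterrows()
    ]

    lists: dict[str, list] = {}
    for modality, fname in SPECTRA_FILES.items():
        df = pd.read_csv(indir / fname)
        grid = _grid_from_columns(modality, list(df.columns))
        cls = EEM if modality == "fluorescence" else Spectrum
        spectra = []
        for i, values in enumerate(df.to_numpy()):
            intensities = values.reshape(grid.shape)
            spectra.append(
                cls(
                    grid,
                    intensities,
                    sample_label=str(meta.loc[i, "sample_label"]),
                    preparation_index=int(meta.loc[i, "preparation_index"]),
                    measurement_index=int(meta.loc[i, "measurement_index"]),
                )
            )
        lists[modality] = spectra
    return SpectraDataset(lists["fluorescence"], lists["nir"], lists["raman"], design)


def write_matrix(X: np.ndarray, meta: pd.DataFrame, path: str | Path,
                 extra_columns: dict[str, np.ndarray] | None = None) -> Path:
    """Write a preprocessed/labelled feature matrix with leading metadata
    columns as a single CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.asarray(X))
    df.columns = [str(c) for c in df.columns]
    lead = meta.reset_index(drop=True)
    if extra_columns:
        for name, col in extra_columns.items():
            lead[name] = col
    out = pd.concat([lead, df], axis=1)
    out.to_csv(path, index=False)
    return path
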