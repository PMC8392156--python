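"""Spectra augmentation and 5-class dataset assembly.

The classification task distinguishes five classes: pure chia oil A, its
adulterations (Adult A), pure chia oil B, its adulterations (Adult B), and
the pure/mixed adulterant oils (Adult).  The two adulteration classes hold
225 real spectra each (15 design labels x 3 preparations x 5 measurements).
The remaining classes are balanced to 225 rows by simulating spectra: a
simulated spectrum perturbs a base spectrum pointwise,

    I~(k) = I(k) + SD(k) * ran(k),

where I(k) is either the per-class mean spectrum or one of the original
spectra, SD(k) the per-class pointwise sample standard deviation and ran(k)
i.i.d. standard-normal draws.

Class A (and B): the 15 original spectra are used five times (75 rows; the
first copy is tagged ``real``, the extra copies ``replicated``) plus 75
mean-based and 75 original-based simulated spectra = 225.  Class Adult: 90
real spectra (S100/R100/C100 and RS50/RC50/SC50), 90 simulated from the 45
pure S/R/C spectra (45 mean-based + 45 original-based) and one extra copy of
the 45 pure adulterant spectra = 225.

Note that the duplicated originals inflate the apparent class support; this
mirrors the assembly being emulated and partly explains near-perfect
training metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import preprocess_dataset
from .synth import SpectraDataset

CLASS_ORDER = ("A", "AdultA", "B", "AdultB", "Adult")

_ADULT_A_LABELS = tuple(
    f"A{o}{p}" for o in ("S", "R", "C") for p in (90, 95, 98, 99)
) + ("AS50", "AR50", "AC50")
_ADULT_B_LABELS = tuple(
    f"B{o}{p}" for o in ("S", "R", "C") for p in (90, 95, 98, 99)
) + ("BS50", "BR50", "BC50")
_ADULT_REAL_LABELS = ("S100", "R100", "C100", "RS50", "RC50", "SC50")
_ADULT_SIM_BASE_LABELS = ("S100", "R100", "C100")

#: Design labels required from the Mexican design, per class.
CLASS_LABELS = {
    "A": ("A100",),
    "AdultA": _ADULT_A_LABELS,
    "B": ("B100",),
    "AdultB": _ADULT_B_LABELS,
    "Adult": _ADULT_REAL_LABELS,
}

TARGET_CLASS_SIZE = 225


@dataclass
class AugmentationRecipe:
    """Inputs of one simulation batch: base spectra and row counts."""

    base_spectra: np.ndarray
    n_mean_based: int
    n_original_based: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_spectra = np.atleast_2d(np.asarray(self.base_spectra, dtype=float))
        if self.base_spectra.size == 0:
            raise ValueError("base spectra set is empty")
        if self.n_mean_based < 0 or self.n_original_based < 0:
            raise ValueError("row counts must be >= 0")

    @property
    def mean_spectrum(self) -> np.ndarray:
        return self.base_spectra.mean(axis=0)

    @property
    def sd_spectrum(self) -> np.ndarray:
        if self.base_spectra.shape[0] < 2:
            return np.zeros(self.base_spectra.shape[1])
        return self.base_spectra.std(axis=0, ddof=1)


def simulate_spectra(recipe: AugmentationRecipe) -> np.ndarray:
    """Simulate spectra by pointwise Gaussian perturbation of the class mean
    (first ``n_mean_based`` rows) and of the originals cycled in order
    (next ``n_original_based`` rows).  Deterministic for a fixed seed."""
    rng = np.random.default_rng(recipe.seed)
    m = recipe.mean_spectrum
    sd = recipe.sd_spectrum
    n_base, p = recipe.base_spectra.shape

    mean_rows = m[None, :] + sd[None, :] * rng.standard_normal((recipe.n_mean_based, p))
    idx = np.arange(recipe.n_original_based) % n_base
    orig_rows = recipe.base_spectra[idx] + sd[None, :] * rng.standard_normal(
        (recipe.n_original_based, p)
    )
    return np.vstack([mean_rows, orig_rows])


@dataclass
class LabeledDataset:
    """Feature matrix with class labels and per-row provenance."""

    X: np.ndarray
    class_labels: np.ndarray       # one of CLASS_ORDER per row
    origin: np.ndarray             # real | replicated | sim_mean | sim_original
    sample_labels: np.ndarray      # design label of real/replicated rows, "" for simulated

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.class_labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X)
        df.insert(0, "class", self.class_labels)
        df.insert(1, "origin", self.origin)
        df.insert(2, "sample_label", self.sample_labels)
        return df


def _rows_for(meta: pd.DataFrame, labels: tuple[str, ...]) -> np.ndarray:
    return meta.index[meta["sample_label"].isin(labels)].to_numpy()


def assemble_classification_set(dataset: SpectraDataset, modality: str = "fused",
                                seed: int = 0) -> LabeledDataset:
    """Assemble the balanced 1125-row, 5-class dataset from a Mexican-design
    dataset (3 preparations x 5 measurements per label).

    Preprocessing (per ``modality``) is applied before augmentation, so the
    simulated spectra live in the same feature space as the real ones.
    """
    X, meta = preprocess_dataset(dataset, modality)
    present = set(meta["sample_label"])
    required = sorted({lab for labs in CLASS_LABELS.values() for lab in labs})
    missing = [lab for lab in required if lab not in present]
    if missing:
        raise ValueError(f"dataset is missing design labels: {', '.join(missing)}")

    rng = np.random.default_rng(seed)
    parts_X: list[np.ndarray] = []
    parts_class: list[np.ndarray] = []
    parts_origin: list[np.ndarray] = []
    parts_label: list[np.ndarray] = []

    def add(rows: np.ndarray, class_id: str, origin: str, labels: np.ndarray) -> None:
        parts_X.append(rows)
        parts_class.append(np.full(len(rows), class_id, dtype=object))
        parts_origin.append(np.full(len(rows), origin, dtype=object))
        parts_label.append(labels)

    # pure-chia classes: originals used five times + 150 simulated
    for class_id in ("A", "B"):
        idx = _rows_for(meta, CLASS_LABELS[class_id])
        base = X[idx]
        base_labels = meta.loc[idx, "sample_label"].to_numpy()
        add(base, class_id, "real", base_labels)
        for _ in range(4):
            add(base, class_id, "replicated", base_labels)
        recipe = AugmentationRecipe(base, 75, 75, seed=int(rng.integers(2**31)))
        sim = simulate_spectra(recipe)
        empty = np.full(75, "", dtype=object)
        add(sim[:75], class_id, "sim_mean", empty)
        add(sim[75:], class_id, "sim_original", empty)

    # adulteration classes: 15 labels x 15 spectra, all real
    for class_id in ("AdultA", "AdultB"):
        idx = _rows_for(meta, CLASS_LABELS[class_id])
        add(X[idx], class_id, "real", meta.loc[idx, "sample_label"].to_numpy())

    # adulterant class: 90 real + 90 simulated from pure S/R/C + 45 replicated
    idx_real = _rows_for(meta, _ADULT_REAL_LABELS)
    add(X[idx_real], "Adult", "real", meta.loc[idx_real, "sample_label"].to_numpy())
    idx_pure = _rows_for(meta, _ADULT_SIM_BASE_LABELS)
    base = X[idx_pure]
    recipe = AugmentationRecipe(base, 45, 45, seed=int(rng.integers(2**31)))
    sim = simulate_spectra(recipe)
    empty = np.full(45, "", dtype=object)
    add(sim[:45], "Adult", "sim_mean", empty)
    add(sim[45:], "Adult", "sim_original", empty)
    add(base, "Adult", "replicated", meta.loc[idx_pure, "sample_label"].to_numpy())

    out = LabeledDataset(
        X=np.vstack(parts_X),
        class_labels=np.concatenate(parts_class),
        origin=np.concatenate(parts_origin),
        sample_labels=np.concatenate(parts_label),
    )
    counts = out.class_counts()
    assert all(counts[c] == TARGET_CLASS_SIZE for c in CLASS_ORDER), counts
    return out
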