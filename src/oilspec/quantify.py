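"""PLSR quantification of adulteration level.

For each oil series (one chia oil and one or all adulterants, e.g. "AS" =
chia A adulterated with sunflower) a partial least squares regression
predicts the adulteration level in mass % from the spectra.  Candidate
latent-variable counts are scored by leave-one-out cross-validation (LOO-CV)
and the count minimising the CV root-mean-square error is selected (ties go
to fewer components).  Reported quality measures are computed from the CV
predictions at the selected count:

* R^2 — coefficient of determination of the CV predictions;
* RMSEP — root-mean-square error of prediction (mass %);
* RMSEP_range — 100 * RMSEP / (max y - min y);
* detection limit — mean + 3 * SD of the CV-predicted adulteration of the
  pure-chia (0 %) samples, the classical 3-sigma blank criterion.

X is mean-centred (no scaling) inside the PLSR; SNV preprocessing already
handles scale for NIR/Raman/fused features.

Numerical note: with n samples and p >> n features, each LOO fit first
projects the centred X onto its row space via an SVD (an exact, loss-free
reduction to at most n coordinates — PLS is equivariant under orthonormal
feature rotation), then fits a single PLS model at the largest candidate
count; regression vectors for all smaller counts are recovered from the
stored weight/loading matrices.  This makes the n_candidates x n_samples
fit grid cost a single PLS fit per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .preprocess import DATASET_MODALITIES, preprocess_dataset
from .synth import SpectraDataset

#: Series of the Mexican design: chia oil -> adulterant(s).
MEXICAN_SERIES: dict[str, tuple[str, tuple[str, ...]]] = {
    "AC": ("A", ("C",)), "AR": ("A", ("R",)), "AS": ("A", ("S",)),
    "A all": ("A", ("S", "R", "C")),
    "BC": ("B", ("C",)), "BR": ("B", ("R",)), "BS": ("B", ("S",)),
    "B all": ("B", ("S", "R", "C")),
}

KENYAN_SERIES: dict[str, tuple[str, tuple[str, ...]]] = {
    oil: (oil, ("S",)) for oil in ("U", "V", "W", "X", "Y", "Z")
}


def series_labels(series_id: str) -> tuple[str, ...]:
    """Design labels contributing to a series (blanks counted once).

    A binary Mexican series such as "AS" holds the pure chia oil, the four
    low-level adulterations, the 50:50 blend and the pure adulterant.  The
    pooled "A all"/"B all" series are the union of the three binary series
    without double-counting the blank.  Kenyan series hold the pure chia oil
    and its 10/50 % sunflower adulterations.
    """
    if series_id in MEXICAN_SERIES:
        chia, adults = MEXICAN_SERIES[series_id]
        labels = [f"{chia}100"]
        for a in adults:
            labels += [f"{chia}{a}{p}" for p in (90, 95, 98, 99)] + [f"{chia}{a}50"]
            labels.append(f"{a}100")
        return tuple(labels)
    if series_id in KENYAN_SERIES:
        oil, _ = KENYAN_SERIES[series_id]
        labels = [f"{oil}100"]
        if oil != "W":              # site W was adulterated only at 50 %
            labels.append(f"{oil}S90")
        labels.append(f"{oil}S50")
        return tuple(labels)
    raise KeyError(f"unknown series {series_id!r}")


@dataclass
class RegressionTask:
    """Spectra matrix and adulteration levels (mass %) for one series."""

    X: np.ndarray
    y: np.ndarray
    series_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y lengths differ")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least 2 distinct adulteration levels")


@dataclass
class PLSResult:
    series_id: str
    modality: str
    n_samples: int
    n_components: int
    r2: float
    rmsep: float
    rmsep_range: float
    detection_limit: float | None
    blank_mean: float | None
    blank_sd: float | None


def rmsep_range(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square prediction error as a percentage of the reference
    range."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    span = y_true.max() - y_true.min()
    if not span > 0:
        raise ValueError("degenerate reference range")
    return 100.0 * float(np.sqrt(np.mean((y_true - y_pred) ** 2))) / float(span)


def detection_limit(blank_predictions: np.ndarray) -> tuple[float, float, float]:
    """3-sigma detection limit from CV-predicted blanks: (mean, SD, dl)."""
    b = np.asarray(blank_predictions, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 blank predictions")
    m = float(b.mean())
    sd = float(b.std(ddof=1))
    return m, sd, m + 3.0 * sd


def _pls_coefficients(pls: PLSRegression, ncomps: list[int]) -> dict[int, np.ndarray]:
    """Regression vectors for truncated component counts of a fitted model.

    B_a = W_a (P_a^T W_a)^{-1} Q_a^T with W/P/Q the x-weights, x-loadings
    and y-loadings of the first a components.
    """
    W = pls.x_weights_
    P = pls.x_loadings_
    Q = pls.y_loadings_      # shape (1, A)
    fitted = W.shape[1]
    out: dict[int, np.ndarray] = {}
    for a in ncomps:
        aa = min(a, fitted)
        R = W[:, :aa] @ np.linalg.pinv(P[:, :aa].T @ W[:, :aa])
        out[a] = (R @ Q[:, :aa].T).ravel()
    return out


def loo_cv_predictions(X: np.ndarray, y: np.ndarray, ncomps: list[int]) -> np.ndarray:
    """Leave-one-out CV predictions, one column per candidate component
    count.  Exact (up to floating point) but accelerated by the SVD row-space
    reduction described in the module docstring."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > max(1e-12 * s[0], 1e-300)).sum()) if s.size else 0
    Z = U[:, :rank] * s[:rank]

    amax = max(ncomps)
    preds = np.empty((n, len(ncomps)))
    for i in range(n):
        Ztr = np.delete(Z, i, axis=0)
        ytr = np.delete(y, i)
        zm = Ztr.mean(axis=0)
        ym = ytr.mean()
        cap = min(amax, Ztr.shape[0] - 1, Ztr.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = PLSRegression(n_components=max(cap, 1), scale=False)
            pls.fit(Ztr, ytr)
        coefs = _pls_coefficients(pls, ncomps)
        z_test = Z[i] - zm
        for j, a in enumerate(ncomps):
            preds[i, j] = ym + float(z_test @ coefs[a])
    return preds


def fit_plsr_cv(task: RegressionTask, ncomp_min: int = 1, ncomp_max: int = 32,
                modality: str = "") -> PLSResult:
    """Select the LOO-CV-optimal component count and report CV quality.

    ``ncomp_max`` must stay below min(n_samples - 1, n_features); component
    counts are scanned from ``ncomp_min`` upward and ties in RMSECV are
    broken towards fewer components.
    """
    n, p = task.X.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    if not (1 <= ncomp_min <= ncomp_max):
        raise ValueError(f"invalid component range [{ncomp_min}, {ncomp_max}]")
    if ncomp_max >= min(n - 1, p):
        raise ValueError(
            f"ncomp_max={ncomp_max} too large for {n} samples / {p} features"
        )
    ncomps = list(range(ncomp_min, ncomp_max + 1))
    preds = loo_cv_predictions(task.X, task.y, ncomps)
    rmse = np.sqrt(np.mean((preds - task.y[:, None]) ** 2, axis=0))
    best_j = int(np.argmin(rmse))          # first minimum -> fewest components
    y_hat = preds[:, best_j]

    ss_res = float(np.sum((task.y - y_hat) ** 2))
    ss_tot = float(np.sum((task.y - task.y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    blanks = y_hat[task.y == 0.0]
    if len(blanks) >= 2:
        m, sd, dl = detection_limit(blanks)
    else:
        m = sd = dl = None
    return PLSResult(
        series_id=task.series_id,
        modality=modality,
        n_samples=n,
        n_components=ncomps[best_j],
        r2=r2,
        rmsep=float(rmse[best_j]),
        rmsep_range=rmsep_range(task.y, y_hat),
        detection_limit=dl,
        blank_mean=m,
        blank_sd=sd,
    )


def build_task(dataset: SpectraDataset, series_id: str, modality: str,
               X_meta: tuple[np.ndarray, pd.DataFrame] | None = None) -> RegressionTask:
    """Extract a series' spectra and adulteration levels from a dataset.

    The response is the total adulterant mass %, i.e. 100 * (1 - fraction of
    the series' chia oil); the pure adulterant samples sit at 100 %.
    """
    labels = series_labels(series_id)
    chia = (MEXICAN_SERIES | KENYAN_SERIES)[series_id][0]
    if X_meta is None:
        X_meta = preprocess_dataset(dataset, modality)
    X, meta = X_meta
    present = set(meta["sample_label"])
    missing = [lab for lab in labels if lab not in present]
    if missing:
        raise ValueError(f"dataset is missing series labels: {', '.join(missing)}")
    mask = meta["sample_label"].isin(labels).to_numpy()
    rows = meta.loc[mask, "sample_label"]
    y = np.round(
        [100.0 * (1.0 - dataset.blend_of(lab).fraction(chia)) for lab in rows], 9
    )
    return RegressionTask(X[mask], y, series_id=series_id)


def quantify_series(dataset: SpectraDataset, series_id: str, modality: str = "fused",
                    X_meta=None) -> PLSResult:
    """PLSR-quantify one series with the design-appropriate component range
    (1-32 for the Mexican series; 3 to min(10, n-2) for the small Kenyan
    series)."""
    task = build_task(dataset, series_id, modality, X_meta=X_meta)
    n = len(task.y)
    if series_id in KENYAN_SERIES:
        ncomp_min, ncomp_max = 3, min(10, n - 2)
    else:
        ncomp_min, ncomp_max = 1, min(32, n - 2)
    return fit_plsr_cv(task, ncomp_min, ncomp_max, modality=modality)


def run_quantification_suite(dataset: SpectraDataset, modality: str = "fused"
                             ) -> pd.DataFrame:
    """One PLSResult row per series present in the dataset (8 Mexican rows
    and/or 6 Kenyan rows) for a given modality."""
    if modality not in DATASET_MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    labels = dataset.labels
    series: list[str] = []
    if "A100" in labels:
        series += list(MEXICAN_SERIES)
    if "U100" in labels:
        series += list(KENYAN_SERIES)
    if not series:
        raise ValueError("dataset contains neither Mexican nor Kenyan series labels")
    X_meta = preprocess_dataset(dataset, modality)
    results = [quantify_series(dataset, sid, modality, X_meta=X_meta) for sid in series]
    return pd.DataFrame(
        {
            "series": [r.series_id for r in results],
            "modality": [r.modality for r in results],
            "n_samples": [r.n_samples for r in results],
            "n_components": [r.n_components for r in results],
            "r2": [r.r2 for r in results],
            "rmsep": [r.rmsep for r in results],
            "rmsep_range": [r.rmsep_range for r in results],
            "detection_limit": [r.detection_limit for r in results],
        }
    )
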