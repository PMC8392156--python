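"""End-to-end orchestration: generate -> preprocess -> augment -> classify /
quantify, with a config file, a manifest and stage-level logging.

A single top-level seed expands into named per-stage seeds through a fixed
splitting rule (``SeedSequence([seed, stage_index])`` reduced below 2^31),
so each stage is independently reproducible.  All outputs are deterministic
CSV/JSON; the manifest records every stage's record counts, seeds and output
SHA-256 hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import augment, classify, io, quantify, synth
from .preprocess import DATASET_MODALITIES, preprocess_dataset

log = logging.getLogger("oilspec")

_STAGES = ("generate", "preprocess", "augment", "classify", "quantify")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    design: str = "mexican"                      # mexican | kenyan | both
    noise_profile: str = "default"               # default | clean
    seed: int = 1
    modalities: tuple[str, ...] = ("fused",)
    classifiers: tuple[str, ...] = classify.METHODS
    n_runs: int = 10
    n_measurements: int = 5
    cv_training_accuracy: bool = True
    quantify_modalities: tuple[str, ...] | None = None   # defaults to `modalities`
    out_dir: str = "oilspec_out"

    def __post_init__(self) -> None:
        for m in self.modalities:
            if m not in DATASET_MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        for c in self.classifiers:
            if c not in classify.METHODS:
                raise ValueError(f"unknown classifier {c!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modalities"] = list(self.modalities)
        d["classifiers"] = list(self.classifiers)
        if self.quantify_modalities is not None:
            d["quantify_modalities"] = list(self.quantify_modalities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("modalities", "classifiers", "quantify_modalities"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; outputs of completed stages are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "stages": {},
        "files": {},
    }

    def record(stage: str, info: dict, paths: list[Path]) -> None:
        manifest["stages"][stage] = info
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
        log.info("stage %s: %s", stage, info)

    # --- generate -----------------------------------------------------
    try:
        gen_seed = stage_seed(config.seed, "generate")
        design = synth.build_design(config.design)
        library = synth.make_endmember_library(gen_seed)
        noise_factory = synth.NOISE_PROFILES[config.noise_profile]
        dataset = synth.generate_dataset(
            design, library, noise=noise_factory(gen_seed),
            n_measurements=config.n_measurements,
        )
        written = io.write_dataset(dataset, out / "spectra")
        record("generate", {"n_rows": len(design),
                            "n_spectra_per_modality": len(dataset.fluorescence)},
               list(written.values()))
    except Exception as e:  # noqa: BLE001
        raise StageError("generate", e) from e

    # --- preprocess ---------------------------------------------------
    try:
        pp_paths = []
        X_cache: dict[str, tuple] = {}
        for modality in config.modalities:
            X, meta = preprocess_dataset(dataset, modality)
            X_cache[modality] = (X, meta)
            pp_paths.append(
                io.write_matrix(X, meta, out / "preprocessed" / f"{modality}.csv")
            )
            prov = out / "preprocessed" / f"{modality}.provenance.json"
            prov.write_text(json.dumps({"modality": modality, "n_rows": int(X.shape[0]),
                                        "n_features": int(X.shape[1])}, indent=2))
            pp_paths.append(prov)
        record("preprocess", {m: X_cache[m][0].shape for m in config.modalities}, pp_paths)
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e

    # --- augment + classify (Mexican 5-class task only) ---------------
    has_mexican = "A100" in dataset.labels
    if has_mexican and config.classifiers:
        try:
            aug_seed = stage_seed(config.seed, "augment")
            aug_paths = []
            for modality in config.modalities:
                labelled = augment.assemble_classification_set(
                    dataset, modality=modality, seed=aug_seed
                )
                aug_paths.append(
                    io.write_matrix(
                        labelled.X,
                        labelled.to_frame()[["class", "origin", "sample_label"]],
                        out / "augmented" / f"{modality}.csv",
                    )
                )
            record("augment", {"rows_per_modality": 5 * augment.TARGET_CLASS_SIZE},
                   aug_paths)
        except Exception as e:  # noqa: BLE001
            raise StageError("augment", e) from e

        try:
            summary: dict = {}
            for modality in config.modalities:
                summary[modality] = {}
                for method in config.classifiers:
                    rs = classify.repeat_runs_augmented(
                        dataset, method, modality=modality, n_runs=config.n_runs,
                        cv_training_accuracy=config.cv_training_accuracy,
                    )
                    summary[modality][method] = {
                        "n_runs": len(rs.per_run),
                        "aggregate": rs.aggregate(),
                        "per_run_tpr": [m.tpr for m in rs.per_run],
                    }
            cls_path = out / "classification_summary.json"
            cls_path.write_text(json.dumps({"schema_version": 1, "results": summary},
                                           indent=2, sort_keys=True))
            n_entries = sum(len(v) for v in summary.values())
            record("classify", {"methods_x_modalities": n_entries}, [cls_path])
        except Exception as e:  # noqa: BLE001
            raise StageError("classify", e) from e
    else:
        manifest["stages"]["classify"] = {"skipped": True}

    # --- quantify -----------------------------------------------------
    try:
        q_mods = config.quantify_modalities or config.modalities
        frames = []
        for modality in q_mods:
            frames.append(quantify.run_quantification_suite(dataset, modality))
        import pandas as pd

        table = pd.concat(frames, ignore_index=True)
        q_path = out / "quantification.csv"
        table.to_csv(q_path, index=False)
        record("quantify", {"n_rows": int(len(table))}, [q_path])
    except Exception as e:  # noqa: BLE001
        raise StageError("quantify", e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
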