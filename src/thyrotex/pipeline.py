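"""End-to-end orchestration: simulate -> segment -> extract -> screen.

`RunConfig` aggregates every pipeline constant (threshold fraction 0.40,
64-level quantization over [0, 20] SUV, AUC pre-selection at 0.55, Fisher
gate at 0.08) so a run is fully described by one JSON-serializable object;
the effective configuration, package versions and seed are echoed to the run
log, and identical config + seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterError
from .features import extract_table
from .imaging import load_volume, segment_nodule
from .phantoms import CohortSpec, default_cohort_spec, make_cohort, write_cohort
from .screening import screen


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                    # "simulate" | "analyze"
    rng_seed: int = 0
    # simulate mode
    cohort: CohortSpec | None = None
    write_volumes: bool = True
    # analyze mode
    input_dir: str | None = None
    cohort_csv: str | None = None
    # segmentation
    threshold_fraction: float = 0.40
    search_radius_mm: float = 15.0
    # quantization
    n_bins: int = 64
    quant_bounds: tuple[float, float] = (0.0, 20.0)
    # feature gating
    min_voxels: int = 64
    # screening gates
    auc_min: float = 0.55
    fisher_alpha: float = 0.08
    anova_alpha: float = 0.05
    n_boot: int = 2000

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ParameterError("threshold_fraction must lie in (0, 1)")
        for gate in (self.auc_min, self.fisher_alpha, self.anova_alpha):
            if not 0.0 < gate < 1.0:
                raise ParameterError("screening gates must lie in (0, 1)")
        if self.mode == "simulate" and self.cohort is None:
            self.cohort = default_cohort_spec(seed=self.rng_seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            from .phantoms import ClassParams

            c = dict(d["cohort"])
            for key in ("benign", "malignant"):
                p = dict(c[key])
                for rk in ("mean_range", "radius_range", "small_radius_range"):
                    p[rk] = tuple(p[rk])
                c[key] = ClassParams(**p)
            for rk in ("grid_shape", "voxel_spacing"):
                c[rk] = tuple(c[rk])
            d["cohort"] = CohortSpec(**c)
        if d.get("quant_bounds") is not None:
            d["quant_bounds"] = tuple(d["quant_bounds"])
        return cls(**d)


def _segment_cohort(volumes, table: pd.DataFrame, config: RunConfig):
    lesions = []
    for grid, (_, row) in zip(volumes, table.iterrows()):
        seed = (int(row["seed_i"]), int(row["seed_j"]), int(row["seed_k"]))
        roi = segment_nodule(
            grid, seed,
            search_radius_mm=config.search_radius_mm,
            threshold_fraction=config.threshold_fraction,
        )
        lesions.append((grid, roi))
    return lesions


def run(config: RunConfig, outdir) -> dict:
    """Execute the pipeline and write its artifact set.

    Artifacts: ``cohort.csv``, ``features.csv`` (+ ``features_meta.json``),
    ``screening.json``, ``predictors.csv``, ``correlation.csv``,
    ``scores.csv`` and ``run_log.json``.  Returns a summary dict.

    Raises with a stage-tagged message on any stage failure; nothing is
    written until the analysis stages have completed.
    """
    outdir = Path(outdir)

    if config.mode == "simulate":
        try:
            phantoms, table = make_cohort(config.cohort)
        except Exception as exc:
            raise ParameterError(f"[simulate] {exc}") from exc
        volumes = [g for g, _, _ in phantoms]
    else:
        if config.input_dir is None or config.cohort_csv is None:
            raise ParameterError("[load] analyze mode needs input_dir and cohort_csv")
        cohort_csv = Path(config.cohort_csv)
        input_dir = Path(config.input_dir)
        if not cohort_csv.exists() or not input_dir.exists():
            raise ParameterError(f"[load] missing input path: {config.cohort_csv} / {config.input_dir}")
        table = pd.read_csv(cohort_csv)
        volumes = []
        for sid in table["subject_id"]:
            path = input_dir / f"{sid}_suv.nii"
            if not path.exists():
                path = input_dir / f"{sid}_suv.nii.gz"
            if not path.exists():
                raise ParameterError(f"[load] missing volume for subject {sid}")
            volumes.append(load_volume(path))

    try:
        lesions = _segment_cohort(volumes, table, config)
    except Exception as exc:
        raise ParameterError(f"[segment] {exc}") from exc

    try:
        feats = extract_table(
            lesions,
            subject_ids=table["subject_id"].tolist(),
            min_voxels=config.min_voxels,
            n_bins=config.n_bins,
            bounds=config.quant_bounds,
        )
    except Exception as exc:
        raise ParameterError(f"[extract] {exc}") from exc

    try:
        report = screen(
            feats,
            table["label"].to_numpy(),
            tir=table["tir_category"].to_numpy() if "tir_category" in table else None,
            auc_min=config.auc_min,
            fisher_alpha=config.fisher_alpha,
            anova_alpha=config.anova_alpha,
            n_boot=config.n_boot,
            seed=config.rng_seed,
        )
    except Exception as exc:
        raise ParameterError(f"[screen] {exc}") from exc

    # all stages succeeded: write artifacts
    outdir.mkdir(parents=True, exist_ok=True)
    if config.mode == "simulate" and config.write_volumes:
        write_cohort(phantoms, table, outdir / "volumes", spec=config.cohort)
    table.to_csv(outdir / "cohort.csv", index=False)
    feats.to_csv(outdir / "features.csv")
    (outdir / "features_meta.json").write_text(json.dumps({
        "n_bins": config.n_bins,
        "quant_bounds": list(config.quant_bounds),
        "threshold_fraction": config.threshold_fraction,
        "min_voxels": config.min_voxels,
    }, indent=2) + "\n")
    (outdir / "screening.json").write_text(report.to_json() + "\n")
    report.predictors_table().to_csv(outdir / "predictors.csv")
    report.correlation_r.to_csv(outdir / "correlation.csv")
    report.scores_table().to_csv(outdir / "scores.csv")
    log = {
        "thyrotex_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")

    return {
        "n_subjects": int(len(table)),
        "preselected": report.preselected,
        "final": report.final,
        "average_ppv": report.average_ppv,
        "average_npv": report.average_npv,
        "outdir": str(outdir),
    }
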