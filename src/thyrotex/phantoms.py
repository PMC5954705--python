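"""Synthetic PET phantoms and cohorts with known class structure.

The generator emulates a cohort of thyroid nodules on FDG-PET: an ellipsoidal
lesion of elevated uptake on a low, noisy background.  Benign nodules draw
their voxel intensities from a symmetric (gaussian) model, malignant nodules
from a right-skewed (lognormal) model with higher uptake, so that the
distributional asymmetry and intensity differ between classes by
construction.  Every phantom carries a ground-truth record with the analytic
moments of its intensity model and its exact ellipsoid volume, which makes
downstream estimators testable without patient data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError, SizingError
from .imaging import RoiMask, VoxelGrid, save_mask, save_volume

INTENSITY_KINDS = ("constant", "gaussian", "lognormal")
CLASS_LABELS = ("benign", "malignant")
TIR_LEVELS = ("TIR1", "TIR2", "TIR3", "TIR4", "TIR5")

#: class-conditional cytology-category probabilities used to simulate the
#: five-level TIR label stream (benign cases are mostly TIR2, malignant cases
#: mostly TIR4/TIR5).  These feed the ANOVA-by-category stage only.
TIR_PROBS = {
    "benign": {"TIR1": 2 / 32, "TIR2": 26 / 32, "TIR3": 4 / 32},
    "malignant": {"TIR3": 3 / 18, "TIR4": 4 / 18, "TIR5": 11 / 18},
}


@dataclass(frozen=True)
class IntensityModel:
    """Voxel-intensity distribution of a nodule, parameterized in SUV.

    ``mean`` and ``sd`` are the analytic mean and standard deviation of the
    distribution (both in SUV), for every kind.  For ``lognormal`` the
    underlying log-scale parameters are solved from (mean, sd), so the
    right-tail heaviness is controlled by the coefficient of variation
    ``sd / mean``.
    """

    kind: str
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in INTENSITY_KINDS:
            raise ParameterError(f"unknown intensity model {self.kind!r}")
        if self.mean < 0 or self.sd < 0:
            raise ParameterError("intensity mean and sd must be non-negative")
        if self.kind == "lognormal" and (self.mean <= 0 or self.sd <= 0):
            raise ParameterError("lognormal model needs positive mean and sd")

    @classmethod
    def lognormal_from_logparams(cls, mu_log: float, sigma_log: float) -> "IntensityModel":
        """Construct a lognormal model from its log-scale location and scale."""
        mean = math.exp(mu_log + sigma_log**2 / 2)
        sd = mean * math.sqrt(math.expm1(sigma_log**2))
        return cls("lognormal", mean, sd)

    @property
    def sigma_log(self) -> float:
        """Log-scale sigma of the lognormal kind (undefined otherwise)."""
        if self.kind != "lognormal":
            raise ParameterError("sigma_log is defined for the lognormal kind only")
        return math.sqrt(math.log1p((self.sd / self.mean) ** 2))

    def analytic_moments(self) -> tuple[float, float, float]:
        """Analytic (mean, sd, skewness) of the model in SUV units.

        Lognormal skewness is ``(e^{s^2} + 2) sqrt(e^{s^2} - 1)`` with ``s``
        the log-scale sigma; the symmetric models have skewness 0.
        """
        if self.kind == "constant":
            return self.mean, 0.0, 0.0
        if self.kind == "gaussian":
            return self.mean, self.sd, 0.0
        s2 = self.sigma_log**2
        skew = (math.exp(s2) + 2.0) * math.sqrt(math.expm1(s2))
        return self.mean, self.sd, skew

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.mean, dtype=np.float64)
        if self.kind == "gaussian":
            return np.clip(rng.normal(self.mean, self.sd, n), 0.0, None)
        s = self.sigma_log
        mu = math.log(self.mean) - s**2 / 2
        return rng.lognormal(mu, s, n)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic PET volume with a single nodule."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_mean: float = 1.0
    background_sd: float = 0.2
    nodule_center_mm: tuple[float, float, float] = (48.0, 48.0, 48.0)
    nodule_radii_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    intensity: IntensityModel = field(default_factory=lambda: IntensityModel("gaussian", 6.0, 1.5))
    class_label: str = "benign"
    rng_seed: int = 0
    smoothing_fwhm_mm: float | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.nodule_radii_mm):
            raise ParameterError("nodule radii must be positive")
        if self.background_mean < 0 or self.background_sd < 0:
            raise ParameterError("background mean/sd must be non-negative")
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(f"class_label must be one of {CLASS_LABELS}")
        # the nodule plus a 2-voxel margin must fit inside the grid
        for n, sp, c, r in zip(
            self.grid_shape, self.voxel_spacing, self.nodule_center_mm, self.nodule_radii_mm
        ):
            if c - r < 2 * sp or c + r > (n - 2) * sp:
                raise SizingError(
                    f"nodule (center {c} mm, radius {r} mm) does not fit in "
                    f"{n} voxels of {sp} mm with a 2-voxel margin"
                )


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    """Voxel-center inclusion test against the nodule ellipsoid."""
    axes = []
    for n, sp, c, r in zip(
        spec.grid_shape, spec.voxel_spacing, spec.nodule_center_mm, spec.nodule_radii_mm
    ):
        centers = (np.arange(n) + 0.5) * sp
        axes.append(((centers - c) / r) ** 2)
    return (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    ) <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, RoiMask, dict]:
    """Render one phantom volume.

    Returns the SUV grid, the true nodule mask (ellipsoid membership by voxel
    center) and a ground-truth record with the analytic moments of the
    intensity model, the exact ellipsoid volume in mL, and the rasterized
    voxel count.  Identical specs (including the seed) give bit-identical
    volumes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    values = np.clip(
        rng.normal(spec.background_mean, spec.background_sd, spec.grid_shape), 0.0, None
    )
    inside = _ellipsoid_mask(spec)
    n_in = int(inside.sum())
    values[inside] = spec.intensity.draw(rng, n_in)
    if spec.smoothing_fwhm_mm:
        sigma = [
            spec.smoothing_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / sp
            for sp in spec.voxel_spacing
        ]
        values = np.clip(ndimage.gaussian_filter(values, sigma), 0.0, None)

    mean, sd, skew = spec.intensity.analytic_moments()
    a, b, c = spec.nodule_radii_mm
    record = {
        "class_label": spec.class_label,
        "rng_seed": spec.rng_seed,
        "analytic_mean": mean,
        "analytic_sd": sd,
        "analytic_skewness": skew,
        "nodule_volume_ml": 4.0 / 3.0 * math.pi * a * b * c / 1000.0,
        "nodule_voxel_count": n_in,
        "center_voxel": tuple(
            int(c / sp) for c, sp in zip(spec.nodule_center_mm, spec.voxel_spacing)
        ),
    }
    grid = VoxelGrid(values, spec.voxel_spacing)
    return grid, RoiMask(inside, spec.voxel_spacing), record


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class ClassParams:
    """Per-class sampling distributions for phantom parameters.

    ``mean_range`` is a uniform range for the nodule mean uptake (SUV);
    the voxel sd is ``cv * mean``.  ``radius_range`` sizes regular nodules
    and ``small_radius_range`` those flagged to fall below the 64-voxel
    gate; ``aspect_jitter`` multiplies each semi-axis by a uniform factor
    in ``[1 - j, 1 + j]``.
    """

    intensity_kind: str
    mean_range: tuple[float, float]
    cv: float
    radius_range: tuple[float, float]
    small_radius_range: tuple[float, float]
    aspect_jitter: float = 0.12


@dataclass(frozen=True)
class CohortSpec:
    """Composition and per-class parameter distributions of a cohort."""

    n_subjects: int = 50
    n_malignant: int = 18
    benign: ClassParams = field(
        default_factory=lambda: ClassParams("gaussian", (4.0, 8.0), 0.25, (11.0, 15.0), (4.5, 7.5))
    )
    malignant: ClassParams = field(
        default_factory=lambda: ClassParams("lognormal", (7.0, 13.0), 0.30, (13.5, 17.0), (5.0, 8.0))
    )
    fraction_small_roi: float = 0.44
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_mean: float = 1.0
    background_sd: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_malignant <= self.n_subjects:
            raise ParameterError("need 0 <= n_malignant <= n_subjects")
        if not 0.0 <= self.fraction_small_roi <= 1.0:
            raise ParameterError("fraction_small_roi must lie in [0, 1]")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study-emulating cohort: 50 subjects, 32 benign / 18 malignant,
    ~44% of nodules sized to fall below the 64-voxel gate."""
    return CohortSpec(rng_seed=seed)


def effect_cohort_spec(seed: int = 0) -> CohortSpec:
    """A cohort with strong injected effects for recovery experiments.

    All nodules are sized above the 64-voxel gate and the classes are well
    separated in uptake (SUVmax), volume (MTV) and intensity-distribution
    asymmetry (skewness), so each of those features carries a true AUC close
    to 1 by construction.
    """
    return CohortSpec(
        benign=ClassParams("gaussian", (4.0, 6.0), 0.25, (11.0, 13.0), (11.0, 13.0)),
        malignant=ClassParams("lognormal", (9.0, 13.0), 0.30, (15.0, 18.0), (15.0, 18.0)),
        fraction_small_roi=0.0,
        rng_seed=seed,
    )


def _sample_tir(rng: np.random.Generator, label: str) -> str:
    probs = TIR_PROBS[label]
    cats = list(probs)
    return cats[rng.choice(len(cats), p=np.array([probs[c] for c in cats]))]


def make_cohort(spec: CohortSpec) -> tuple[list[tuple[VoxelGrid, RoiMask, dict]], pd.DataFrame]:
    """Generate a cohort of phantoms and its subject table.

    Exactly ``n_malignant`` subjects are malignant; each subject is
    independently flagged "small" with probability ``fraction_small_roi``
    (its radii are then drawn from ``small_radius_range``, sized to yield an
    ROI below 64 voxels at the 40% threshold).  The table holds subject id,
    class label, simulated TIR category, per-subject rng seed, the seed voxel
    for segmentation, and the ground-truth columns of each phantom record.
    Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    labels = np.array(
        ["malignant"] * spec.n_malignant + ["benign"] * (spec.n_subjects - spec.n_malignant)
    )
    rng.shuffle(labels)

    phantoms: list[tuple[VoxelGrid, RoiMask, dict]] = []
    rows = []
    center = tuple((n / 2.0) * sp for n, sp in zip(spec.grid_shape, spec.voxel_spacing))
    for i, label in enumerate(labels):
        params: ClassParams = getattr(spec, label)
        small = bool(rng.random() < spec.fraction_small_roi)
        rrange = params.small_radius_range if small else params.radius_range
        base_r = rng.uniform(*rrange)
        jitter = rng.uniform(1 - params.aspect_jitter, 1 + params.aspect_jitter, 3)
        radii = tuple(float(base_r * j) for j in jitter)
        mean = float(rng.uniform(*params.mean_range))
        model = IntensityModel(params.intensity_kind, mean, params.cv * mean)
        tir = _sample_tir(rng, label)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        pspec = PhantomSpec(
            grid_shape=spec.grid_shape,
            voxel_spacing=spec.voxel_spacing,
            background_mean=spec.background_mean,
            background_sd=spec.background_sd,
            nodule_center_mm=center,
            nodule_radii_mm=radii,
            intensity=model,
            class_label=str(label),
            rng_seed=subject_seed,
        )
        grid, mask, record = make_phantom(pspec)
        record["small_roi"] = small
        phantoms.append((grid, mask, record))
        ci, cj, ck = record["center_voxel"]
        rows.append(
            {
                "subject_id": f"S{i:03d}",
                "label": str(label),
                "tir_category": tir,
                "seed": subject_seed,
                "seed_i": ci,
                "seed_j": cj,
                "seed_k": ck,
                "small_roi": small,
                "true_mean": record["analytic_mean"],
                "true_sd": record["analytic_sd"],
                "true_skewness": record["analytic_skewness"],
                "true_volume_ml": record["nodule_volume_ml"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "label", "tir_category", "seed", "seed_i", "seed_j",
            "seed_k", "small_roi", "true_mean", "true_sd", "true_skewness",
            "true_volume_ml",
        ],
    )
    return phantoms, table


def write_cohort(
    phantoms: list[tuple[VoxelGrid, RoiMask, dict]],
    table: pd.DataFrame,
    outdir,
    spec: CohortSpec | None = None,
    compress: bool = False,
) -> None:
    """Write volumes/masks as NIfTI, the cohort table as CSV, and echo the
    generation parameters to a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    for (grid, mask, _), sid in zip(phantoms, table["subject_id"]):
        save_volume(grid, outdir / f"{sid}_suv{ext}")
        save_mask(mask, outdir / f"{sid}_truemask{ext}")
    table.to_csv(outdir / "cohort.csv", index=False)
    if spec is not None:
        (outdir / "cohort_params.json").write_text(
            json.dumps(asdict(spec), indent=2, default=str) + "\n"
        )
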