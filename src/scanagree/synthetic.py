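"""Synthetic study data: simulated volume tables and geometric head phantoms.

The real study design this package analyses — ten subjects, each scanned
twice on three MRI systems within two hours, with eleven brain structures
quantified per scan — is not publicly redistributable, so two generators
stand in for it:

``simulate_volume_table``
    draws long-format volume tables from the variance model the agreement
    analysis assumes:

        v[subject, scanner, rep] = bias[scanner] * (mu + u_subject) * (1 + eps)

    with ``u ~ N(0, between_subject_sd^2)`` shared across all scans of a
    subject for one structure, and ``eps ~ N(0, (residual_cv/100)^2)`` drawn
    independently per measurement (multiplicative scan-rescan noise, so the
    noise CV is scale-free across structures spanning 3 mL to 1.1 L).

``generate_phantom_pair``
    builds pairs of 3D T1w-like images as nested ellipsoid shells
    (CSF/GM/WM plus two hippocampus-like blobs) with a known ground-truth
    affine between them, known tissue contrast and additive Gaussian noise —
    enough structure to exercise affine registration, NMI similarity, CNR
    and Dice overlap with an exact oracle transform.

Defaults reproduce the study conditions: 10 subjects x 3 scanners x
2 repetitions x 11 structures, population means/SDs from the published
all-scanner volume table, per-scanner multiplicative bias from the published
per-scanner means, and a residual CV calibrated so the expected mean
scan-rescan pair CV (sqrt(2/pi) times the noise CV) matches the published
~1.05% grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import published
from .geometry import AffineTransform, ImageVolume, LabelMap
from .records import VolumeRecord

__all__ = [
    "SimulationConfig",
    "PhantomConfig",
    "PhantomPair",
    "simulate_volume_table",
    "generate_phantom_pair",
    "PHANTOM_LABEL_NAMES",
    "default_structures",
    "default_scanner_bias",
]

#: expected mean of a half-normal |d|/sd, used to calibrate the default CV
_HALF_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))

#: mean pair-CV target (%) across structures, from the published intra-scanner
#: grand means (1.05, 1.15, 0.95)
_TARGET_MEAN_PAIR_CV = 1.05

#: residual noise CV (%) such that sqrt(2/pi) * cv == target mean pair CV
DEFAULT_RESIDUAL_CV_PERCENT = _TARGET_MEAN_PAIR_CV / _HALF_NORMAL_MEAN


def default_structures() -> list[tuple[str, float, float]]:
    """(name, population mean mL, between-subject SD mL) for the 11 structures."""
    return [
        (name, *published.ACTUAL_VOLUMES_ML[name]) for name in published.STRUCTURES
    ]


def default_scanner_bias() -> dict[str, dict[str, float]]:
    """Per-scanner multiplicative bias: published scanner mean / pooled mean."""
    return {
        scanner: {
            name: published.SCANNER_MEAN_VOLUMES_ML[scanner][name]
            / published.ACTUAL_VOLUMES_ML[name][0]
            for name in published.STRUCTURES
        }
        for scanner in published.SCANNERS
    }


@dataclass
class SimulationConfig:
    """Generative parameters for a simulated multi-scanner volume table."""

    n_subjects: int = 10
    scanners: tuple = published.SCANNERS
    n_repetitions: int = 2
    structures: list = field(default_factory=default_structures)
    scanner_bias: dict = field(default_factory=default_scanner_bias)
    residual_cv_percent: float = DEFAULT_RESIDUAL_CV_PERCENT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.n_repetitions < 2:
            raise ValueError("need at least two repetitions")
        if not self.scanners:
            raise ValueError("need at least one scanner")
        if self.residual_cv_percent < 0:
            raise ValueError("residual_cv_percent must be >= 0")
        for name, mean, sd in self.structures:
            if mean <= 0 or sd <= 0:
                raise ValueError(f"structure {name!r}: mean and SD must be > 0")
        for scanner, per_structure in self.scanner_bias.items():
            for name, factor in per_structure.items():
                if factor <= 0:
                    raise ValueError(f"bias for {scanner}/{name} must be > 0")

    def bias(self, scanner: str, structure: str) -> float:
        return float(self.scanner_bias.get(scanner, {}).get(structure, 1.0))


def simulate_volume_table(config: SimulationConfig) -> list[VolumeRecord]:
    """Draw one complete balanced volume table.

    Deterministic for a fixed seed.  Non-positive draws (possible in the
    Gaussian tails, e.g. lateral ventricles at CV ~34%) are resampled rather
    than clipped, so no point mass appears at zero.
    """
    rng = np.random.default_rng(config.seed)
    noise_sd = config.residual_cv_percent / 100.0
    records: list[VolumeRecord] = []
    subjects = [f"sub{idx + 1:03d}" for idx in range(config.n_subjects)]
    for name, mean, sd in config.structures:
        true_volumes = mean + sd * rng.standard_normal(config.n_subjects)
        # resample subjects whose true volume is non-positive
        bad = true_volumes <= 0
        while np.any(bad):
            true_volumes[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
            bad = true_volumes <= 0
        for subject, true_volume in zip(subjects, true_volumes):
            for scanner in config.scanners:
                bias = config.bias(scanner, name)
                for rep in range(1, config.n_repetitions + 1):
                    volume = 0.0
                    while volume <= 0:
                        eps = noise_sd * rng.standard_normal()
                        volume = bias * true_volume * (1.0 + eps)
                    records.append(
                        VolumeRecord(
                            subject_id=subject,
                            scanner_id=scanner,
                            repetition=rep,
                            structure=name,
                            volume_ml=float(volume),
                        )
                    )
    return records


# --------------------------------------------------------------------------
# phantom images

#: label ids of the phantom compartments
PHANTOM_LABEL_NAMES = {
    1: "csf",
    2: "gray_matter",
    3: "white_matter",
    4: "hippocampus_left",
    5: "hippocampus_right",
}


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise of a synthetic head phantom pair."""

    grid_shape: tuple = (64, 64, 64)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    #: outer semi-axes (mm) of the nested CSF/GM/WM ellipsoid shells
    shell_radii_mm: dict = field(
        default_factory=lambda: {
            "csf": (55.0, 48.0, 42.0),
            "gm": (48.0, 42.0, 36.0),
            "wm": (38.0, 32.0, 27.0),
        }
    )
    #: centers of the two hippocampus-like blobs (inside the WM shell);
    #: empty tuple disables them
    hippocampus_centers_mm: tuple = ((-18.0, 5.0, -5.0), (18.0, 5.0, -5.0))
    hippocampus_radii_mm: tuple = (7.0, 5.0, 5.0)
    tissue_means: dict = field(
        default_factory=lambda: {"background": 0.0, "csf": 20.0, "gm": 70.0, "wm": 100.0}
    )
    noise_sd: float = 2.0
    contrast_scale: float = 1.0
    true_affine: AffineTransform = field(default_factory=AffineTransform.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        csf = np.asarray(self.shell_radii_mm["csf"])
        gm = np.asarray(self.shell_radii_mm["gm"])
        wm = np.asarray(self.shell_radii_mm["wm"])
        if not (np.all(csf > gm) and np.all(gm > wm)):
            raise ValueError("shell radii must be strictly nested csf > gm > wm")
        half_extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm) / 2.0
        if np.any(csf >= half_extent):
            raise ValueError("outer shell does not fit inside the image grid")


@dataclass
class PhantomPair:
    """Two images of the same phantom related by a known affine.

    ``true_affine`` maps physical coordinates of image_a to those of
    image_b; each image carries its own label map on its own grid.
    """

    image_a: ImageVolume
    image_b: ImageVolume
    labels_a: LabelMap
    labels_b: LabelMap
    true_affine: AffineTransform


def _inside_ellipsoid(points: np.ndarray, radii, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    rel = (points - np.asarray(center, dtype=float)) / np.asarray(radii, dtype=float)
    return np.einsum("...i,...i->...", rel, rel) <= 1.0


def _template_labels(points: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Evaluate the analytic phantom label field at physical points."""
    labels = np.zeros(points.shape[:-1], dtype=np.int32)
    labels[_inside_ellipsoid(points, config.shell_radii_mm["csf"])] = 1
    labels[_inside_ellipsoid(points, config.shell_radii_mm["gm"])] = 2
    wm = _inside_ellipsoid(points, config.shell_radii_mm["wm"])
    labels[wm] = 3
    for label_id, center in zip((4, 5), config.hippocampus_centers_mm):
        hip = _inside_ellipsoid(points, config.hippocampus_radii_mm, center) & wm
        labels[hip] = label_id
    return labels


def _intensity_from_labels(labels: np.ndarray, config: PhantomConfig, contrast_scale: float) -> np.ndarray:
    means = config.tissue_means
    gm_mean = means["wm"] + contrast_scale * (means["gm"] - means["wm"])
    lut = np.array(
        [means["background"], means["csf"], gm_mean, means["wm"], gm_mean, gm_mean]
    )
    return lut[labels]


def generate_phantom_pair(config: PhantomConfig) -> PhantomPair:
    """Generate both images of a phantom pair, deterministic for a seed.

    Image B is the analytic template evaluated through the inverse of the
    ground-truth affine (exact, no interpolation error) with its own fresh
    noise and optionally rescaled GM-WM contrast; both label maps come from
    the same analytic geometry, so their per-structure volumes agree up to
    voxelization error.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(n) for n in config.grid_shape)
    spacing = np.asarray(config.spacing_mm, dtype=float)
    origin = -(np.asarray(shape, dtype=float) - 1.0) / 2.0 * spacing

    grid = ImageVolume(voxels=np.zeros(shape), spacing_mm=spacing, origin_mm=origin)
    points = grid.physical_grid()

    labels_a = _template_labels(points, config)
    intensity_a = _intensity_from_labels(labels_a, config, 1.0)
    image_a = ImageVolume(
        voxels=intensity_a + config.noise_sd * rng.standard_normal(shape),
        spacing_mm=spacing,
        origin_mm=origin,
    )

    inv = config.true_affine.inverse()
    points_b = inv.apply(points)
    labels_b = _template_labels(points_b, config)
    intensity_b = _intensity_from_labels(labels_b, config, config.contrast_scale)
    image_b = ImageVolume(
        voxels=intensity_b + config.noise_sd * rng.standard_normal(shape),
        spacing_mm=spacing,
        origin_mm=origin,
    )

    return PhantomPair(
        image_a=image_a,
        image_b=image_b,
        labels_a=LabelMap(
            labels=labels_a, spacing_mm=spacing, origin_mm=origin, names=dict(PHANTOM_LABEL_NAMES)
        ),
        labels_b=LabelMap(
            labels=labels_b, spacing_mm=spacing, origin_mm=origin, names=dict(PHANTOM_LABEL_NAMES)
        ),
        true_affine=config.true_affine,
    )
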