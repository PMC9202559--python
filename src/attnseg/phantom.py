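"""Synthetic BraTS-like multimodal phantoms with nested tumor labels.

A phantom is an ellipsoidal "brain" embedded in a zero background, with a
tumor built from three concentric spheres: whole (edema envelope) > core
(necrotic) > enhancing.  Voxel classes follow the BraTS convention used
throughout the package:

====  =========================
label  meaning
====  =========================
0      background / healthy (non-tumor)
1      necrotic core tissue
2      edema
3      enhancing tumor
====  =========================

Evaluation regions are composites: WT = {1,2,3}, TC = {1,3}, ET = {3},
nested by construction (the spheres are concentric).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

#: Canonical modality order used for channel stacking everywhere.
MODALITIES = ("t1", "t1ce", "t2", "flair")

#: Voxel classes inside the brain, indexed by label value.
#: Per-modality mean intensity for classes (healthy, core, edema, enhancing).
#: Chosen so that FLAIR(edema) > FLAIR(healthy) and T1ce(enhancing) > T1ce(core).
DEFAULT_TISSUE_MEANS: dict[str, tuple[float, float, float, float]] = {
    "t1": (120.0, 80.0, 90.0, 100.0),
    "t1ce": (120.0, 70.0, 90.0, 200.0),
    "t2": (100.0, 140.0, 160.0, 120.0),
    "flair": (110.0, 120.0, 180.0, 130.0),
}


class PhantomSpecError(ValueError):
    """Raised when a :class:`PhantomSpec` violates its invariants."""


@dataclass(frozen=True)
class LabelMask:
    """Integer voxel labels in {0, 1, 2, 3}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        bad = np.setdiff1d(np.unique(arr), [0, 1, 2, 3])
        if bad.size:
            raise ValueError(f"label values outside {{0,1,2,3}}: {bad.tolist()}")
        object.__setattr__(self, "labels", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass(frozen=True)
class CaseBundle:
    """One subject: four co-registered modality volumes + optional mask."""

    modalities: Mapping[str, np.ndarray]
    mask: Optional[LabelMask]
    affine: np.ndarray
    case_id: str

    def __post_init__(self) -> None:
        if tuple(self.modalities.keys()) != MODALITIES:
            raise ValueError(
                f"modalities must be ordered {MODALITIES}, got {tuple(self.modalities)}"
            )
        shapes = {m: v.shape for m, v in self.modalities.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"modality shapes disagree: {shapes}")
        if self.mask is not None and self.mask.shape != self.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != volume shape {self.shape}"
            )
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.modalities.values())).shape


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``region_radii`` are (whole, core, enhancing) radii in world units
    (voxel index * ``spacing``), strictly decreasing.  The largest sphere
    must fit inside the brain ellipsoid.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    brain_radius_frac: float = 0.45
    tumor_center: tuple[int, int, int] = (40, 56, 8)
    region_radii: tuple[float, float, float] = (12.0, 8.0, 4.0)
    tissue_means: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize sequence fields so specs survive YAML/JSON round trips
        for name in ("grid_shape", "spacing", "tumor_center", "region_radii"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        object.__setattr__(
            self,
            "tissue_means",
            {m: tuple(v) for m, v in dict(self.tissue_means).items()},
        )
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise PhantomSpecError(f"bad grid_shape {self.grid_shape}")
        r_whole, r_core, r_enh = self.region_radii
        if not (r_whole > r_core > r_enh > 0):
            raise PhantomSpecError(
                f"region_radii must be strictly decreasing and positive, got {self.region_radii}"
            )
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if not 0 < self.brain_radius_frac <= 0.5:
            raise PhantomSpecError("brain_radius_frac must be in (0, 0.5]")
        if set(self.tissue_means) != set(MODALITIES):
            raise PhantomSpecError(
                f"tissue_means must cover modalities {MODALITIES}"
            )
        for m, means in self.tissue_means.items():
            if len(means) != 4:
                raise PhantomSpecError(
                    f"tissue_means[{m!r}] needs 4 entries (healthy, core, edema, enhancing)"
                )
        # Conservative per-axis fit check: tumor sphere inside brain ellipsoid.
        for ax in range(3):
            semi = self.brain_radius_frac * self.grid_shape[ax] * self.spacing[ax]
            off = abs(self.tumor_center[ax] - (self.grid_shape[ax] - 1) / 2.0)
            if off * self.spacing[ax] + r_whole > semi:
                raise PhantomSpecError(
                    f"tumor sphere (r={r_whole}) does not fit inside the brain "
                    f"ellipsoid along axis {ax}"
                )

    @property
    def brain_semi_axes(self) -> tuple[float, float, float]:
        """World-unit semi-axes of the brain ellipsoid."""
        return tuple(
            self.brain_radius_frac * n * s
            for n, s in zip(self.grid_shape, self.spacing)
        )


def _world_distance_sq(spec: PhantomSpec, center: Sequence[float]) -> np.ndarray:
    """Squared world-unit distance of every voxel center from ``center`` (voxel coords)."""
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in spec.grid_shape], indexing="ij"
    )
    d2 = np.zeros(spec.grid_shape, dtype=float)
    for g, c, s in zip(grids, center, spec.spacing):
        d2 += ((g - c) * s) ** 2
    return d2


def _label_volume(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, brain_mask) for the analytic geometry of ``spec``."""
    r_whole, r_core, r_enh = spec.region_radii
    d2 = _world_distance_sq(spec, spec.tumor_center)

    grid_center = [(n - 1) / 2.0 for n in spec.grid_shape]
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in spec.grid_shape], indexing="ij"
    )
    ell = np.zeros(spec.grid_shape, dtype=float)
    for ax, (g, c) in enumerate(zip(grids, grid_center)):
        ell += (((g - c) * spec.spacing[ax]) / spec.brain_semi_axes[ax]) ** 2
    brain = ell <= 1.0

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[d2 <= r_whole**2] = 2  # edema envelope
    labels[d2 <= r_core**2] = 1  # necrotic core
    labels[d2 <= r_enh**2] = 3  # enhancing
    labels[~brain] = 0
    return labels, brain


def generate_phantom(spec: PhantomSpec) -> CaseBundle:
    """Generate one synthetic case from ``spec``.

    Each modality volume is the per-voxel tissue-mean lookup plus i.i.d.
    Gaussian noise with sd ``spec.noise_sd``; voxels outside the brain
    ellipsoid have mean 0.  Deterministic for a fixed spec + seed.
    """
    labels, brain = _label_volume(spec)
    rng = np.random.default_rng(spec.seed)

    modalities: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        means = np.asarray(spec.tissue_means[m], dtype=float)
        vol = np.where(brain, means[labels], 0.0)
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        modalities[m] = vol.astype(np.float32)

    affine = np.diag([*spec.spacing, 1.0])
    return CaseBundle(
        modalities=modalities,
        mask=LabelMask(labels.astype(np.int16)),
        affine=affine,
        case_id=f"phantom-{spec.seed:04d}",
    )


def phantom_cohort(n: int, base_spec: PhantomSpec | None = None, seed: int = 0) -> list[CaseBundle]:
    """Generate ``n`` cases with jittered tumor centers and radii.

    Jitter: tumor center +-3 voxels in-plane, +-1 along the third axis;
    radii scaled by a common factor in [0.9, 1.1].  If the full jitter
    would push the tumor outside the brain ellipsoid, the jitter is
    reduced (drop the through-plane shift, then the radius growth, then
    all center shift) so every case stays valid.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    spec = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for k in range(n):
        dx, dy = (int(v) for v in rng.integers(-3, 4, size=2))
        dz = int(rng.integers(-1, 2))
        scale = float(rng.uniform(0.9, 1.1))
        case_seed = int(rng.integers(0, 2**31 - 1))
        jittered = None
        for cx, cy, cz, s in (
            (dx, dy, dz, scale),
            (dx, dy, 0, scale),
            (dx, dy, 0, min(scale, 1.0)),
            (0, 0, 0, 1.0),
        ):
            try:
                jittered = dataclasses.replace(
                    spec,
                    tumor_center=(
                        spec.tumor_center[0] + cx,
                        spec.tumor_center[1] + cy,
                        spec.tumor_center[2] + cz,
                    ),
                    region_radii=tuple(r * s for r in spec.region_radii),
                    seed=case_seed,
                )
                break
            except PhantomSpecError:
                continue
        if jittered is None:
            raise PhantomSpecError(
                "base spec leaves no room for the tumor even without jitter"
            )
        case = generate_phantom(jittered)
        cases.append(
            dataclasses.replace(case, case_id=f"phantom-{seed:04d}-{k:03d}")
        )
    return cases
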