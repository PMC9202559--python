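"""NIfTI case I/O, intensity normalization, and patch extraction.

Cases follow the BraTS layout: four co-registered modality volumes plus
one integer label mask, stored as ``{case_id}_{t1,t1ce,t2,flair,seg}.nii[.gz]``.
Native label 4 (enhancing in raw BraTS files) is remapped to 3 on read so
all downstream code sees labels in {0, 1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np

from attnseg.phantom import MODALITIES, CaseBundle, LabelMask

#: raw BraTS label 4 -> internal label 3 (enhancing)
LABEL_REMAP = {0: 0, 1: 1, 2: 2, 3: 3, 4: 3}


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


@dataclass(frozen=True)
class PatchSet:
    """Aligned image/mask slice pairs ready for training.

    ``images``: (N, H, W, 4) float32, channels ordered (T1, T1ce, T2, FLAIR);
    ``masks``: (N, H, W) integer labels; ``provenance``: (case_id, axial index)
    per patch.
    """

    images: np.ndarray
    masks: np.ndarray
    provenance: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.images.ndim != 4 or self.images.shape[-1] != len(MODALITIES):
            raise ValueError(f"images must be (N, H, W, 4), got {self.images.shape}")
        if self.masks.shape != self.images.shape[:3]:
            raise ValueError(
                f"masks shape {self.masks.shape} misaligned with images "
                f"{self.images.shape[:3]}"
            )
        if len(self.provenance) != len(self.images):
            raise ValueError("provenance must have one entry per patch")
        bad = np.setdiff1d(np.unique(self.masks), [0, 1, 2, 3])
        if bad.size:
            raise ValueError(f"mask values outside {{0,1,2,3}}: {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.images)


def remap_labels(labels: np.ndarray) -> np.ndarray:
    """Map raw BraTS labels {0,1,2,4} onto {0,1,2,3}; reject anything else."""
    labels = np.asarray(labels)
    observed = np.unique(labels)
    bad = np.setdiff1d(observed, list(LABEL_REMAP))
    if bad.size:
        raise FormatError(f"label values outside {{0,1,2,3,4}}: {bad.tolist()}")
    out = labels.astype(np.int16, copy=True)
    out[labels == 4] = 3
    return out


def read_case(
    modality_paths: Mapping[str, str | Path],
    mask_path: str | Path | None = None,
    case_id: str | None = None,
) -> CaseBundle:
    """Read four modality NIfTI files (+ optional mask) into a CaseBundle."""
    missing = set(MODALITIES) - set(modality_paths)
    if missing:
        raise FormatError(f"missing modalities: {sorted(missing)}")
    volumes: dict[str, np.ndarray] = {}
    affine = None
    for m in MODALITIES:
        img = nib.load(str(modality_paths[m]))
        vol = np.asarray(img.get_fdata(), dtype=np.float32)
        if affine is None:
            affine = img.affine
        if volumes and vol.shape != next(iter(volumes.values())).shape:
            shapes = {k: v.shape for k, v in volumes.items()}
            raise FormatError(
                f"shape mismatch: {m} is {vol.shape}, others are {shapes}"
            )
        volumes[m] = vol
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        raw = np.asarray(mimg.get_fdata())
        if not np.allclose(raw, np.round(raw)):
            raise FormatError("mask volume contains non-integer values")
        labels = remap_labels(np.round(raw).astype(np.int16))
        if labels.shape != next(iter(volumes.values())).shape:
            raise FormatError(
                f"mask shape {labels.shape} != modality shape "
                f"{next(iter(volumes.values())).shape}"
            )
        mask = LabelMask(labels)
    if case_id is None:
        case_id = Path(str(modality_paths[MODALITIES[0]])).name.split("_")[0]
    return CaseBundle(modalities=volumes, mask=mask, affine=affine, case_id=case_id)


def case_paths(case_dir: str | Path, case_id: str) -> tuple[dict[str, Path], Path]:
    """Resolve the conventional file layout for one case id."""
    case_dir = Path(case_dir)

    def find(stem: str) -> Path:
        for ext in (".nii.gz", ".nii"):
            p = case_dir / f"{case_id}_{stem}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(f"no {case_id}_{stem}.nii[.gz] under {case_dir}")

    return {m: find(m) for m in MODALITIES}, case_dir / f"{case_id}_seg.nii.gz"


def write_case(case: CaseBundle, out_dir: str | Path) -> list[Path]:
    """Write a case as {case_id}_{t1,t1ce,t2,flair,seg}.nii.gz files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for m in MODALITIES:
        p = out_dir / f"{case.case_id}_{m}.nii.gz"
        nib.save(nib.Nifti1Image(case.modalities[m].astype(np.float32), case.affine), p)
        written.append(p)
    if case.mask is not None:
        written.append(write_mask(case.mask.labels, case.affine, out_dir / f"{case.case_id}_seg.nii.gz"))
    return written


def write_mask(labels: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write an integer label volume as uint8 NIfTI with the source affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(labels).astype(np.uint8), affine), path)
    return path


def zscore_normalize(volume: np.ndarray) -> np.ndarray:
    """Z-score over nonzero (brain) voxels with the population sd; zeros stay 0.

    Raises on volumes whose nonzero support is absent or constant.
    """
    volume = np.asarray(volume, dtype=np.float64)
    support = volume != 0
    n = int(support.sum())
    if n < 2:
        raise ValueError("need >= 2 nonzero voxels to normalize")
    vals = volume[support]
    mean = vals.mean()
    sd = vals.std()  # population convention (ddof=0)
    if sd < 1e-12:
        raise ValueError("nonzero region is constant; cannot normalize")
    out = np.zeros_like(volume)
    out[support] = (vals - mean) / sd
    return out.astype(np.float32)


def _crop_pad_2d(sl: np.ndarray, size: int, fill: float = 0.0) -> np.ndarray:
    """Center-crop/zero-pad the first two axes of ``sl`` to size x size."""
    out_shape = (size, size) + sl.shape[2:]
    out = np.full(out_shape, fill, dtype=sl.dtype)
    src, dst = [], []
    for ax in range(2):
        n = sl.shape[ax]
        if n >= size:
            start = (n - size) // 2
            src.append(slice(start, start + size))
            dst.append(slice(0, size))
        else:
            start = (size - n) // 2
            src.append(slice(0, n))
            dst.append(slice(start, start + n))
    out[dst[0], dst[1]] = sl[src[0], src[1]]
    return out


def extract_patches(
    case: CaseBundle,
    size: int = 224,
    tumor_fraction: float = 0.5,
    num_patches: int | None = None,
    seed: int = 0,
    normalize: bool = True,
) -> PatchSet:
    """Sample axial slices as size x size multimodal patches.

    At least ``ceil(tumor_fraction * N)`` of the N returned patches contain
    at least one tumor voxel; sampling (with replacement across draws of
    the same pool when N exceeds the pool) is seeded and reproducible.
    """
    if case.mask is None:
        raise ValueError("patch extraction needs a label mask")
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor_fraction must be in [0, 1]")
    depth = case.shape[2]
    if num_patches is None:
        num_patches = depth
    if num_patches < 1:
        raise ValueError("num_patches must be >= 1")

    labels = case.mask.labels
    tumor_slices = [k for k in range(depth) if (labels[:, :, k] > 0).any()]
    n_tumor_needed = int(np.ceil(tumor_fraction * num_patches))
    if n_tumor_needed > 0 and not tumor_slices:
        raise ValueError("tumor_fraction > 0 but the case has no tumor voxels")

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    if n_tumor_needed > 0:
        chosen.extend(
            rng.choice(tumor_slices, size=n_tumor_needed, replace=True).tolist()
        )
    n_rest = num_patches - n_tumor_needed
    if n_rest > 0:
        chosen.extend(rng.choice(depth, size=n_rest, replace=True).tolist())

    if normalize:
        vols = {m: zscore_normalize(case.modalities[m]) for m in MODALITIES}
    else:
        vols = {m: case.modalities[m].astype(np.float32) for m in MODALITIES}

    images, masks, prov = [], [], []
    for k in chosen:
        channels = np.stack([vols[m][:, :, k] for m in MODALITIES], axis=-1)
        images.append(_crop_pad_2d(channels.astype(np.float32), size))
        masks.append(_crop_pad_2d(labels[:, :, k], size))
        prov.append((case.case_id, int(k)))
    return PatchSet(
        images=np.stack(images),
        masks=np.stack(masks).astype(np.int16),
        provenance=tuple(prov),
    )


def extract_patches_cohort(
    cases: Sequence[CaseBundle],
    size: int = 224,
    tumor_fraction: float = 0.5,
    patches_per_case: int | None = None,
    seed: int = 0,
    normalize: bool = True,
) -> PatchSet:
    """Concatenate per-case patch sets with per-case derived seeds."""
    if not cases:
        raise ValueError("no cases given")
    sets = [
        extract_patches(
            case,
            size=size,
            tumor_fraction=tumor_fraction,
            num_patches=patches_per_case,
            seed=seed + i,
            normalize=normalize,
        )
        for i, case in enumerate(cases)
    ]
    return PatchSet(
        images=np.concatenate([s.images for s in sets]),
        masks=np.concatenate([s.masks for s in sets]),
        provenance=tuple(p for s in sets for p in s.provenance),
    )
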