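"""Train / predict / evaluate orchestration for the segmentation pipeline.

Stage order: the attention gates live inside the network; Gaussian noise
injection (onto the decoder logits) is an optional training-time
regularizer, and Ising-MRF polishing is an optional inference-time
post-process applied per tumor class and recombined by priority
enhancing > core > edema.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from attnseg.attention_unet import (
    Adam,
    AttentionUNet,
    NetworkConfig,
    build_segmenter,
    softmax_cross_entropy,
)
from attnseg.metrics import REGIONS, MetricsReport, evaluate_masks
from attnseg.mrf_polish import MRFConfig, from_bipolar, icm_denoise, inject_noise
from attnseg.nifti_io import (
    MODALITIES,
    PatchSet,
    _crop_pad_2d,
    case_paths,
    extract_patches_cohort,
    read_case,
    zscore_normalize,
)
from attnseg.phantom import CaseBundle, LabelMask, PhantomSpec, phantom_cohort

logger = logging.getLogger("attnseg")

#: recombination priority when polished per-class maps overlap
CLASS_PRIORITY = (3, 1, 2)  # enhancing > core > edema


@dataclass(frozen=True)
class TrainingConfig:
    loss: str = "cross_entropy"
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_steps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_steps < 1:
            raise ValueError("learning_rate, batch_size, max_steps must be positive")


@dataclass(frozen=True)
class DataConfig:
    case_dir: Optional[str] = None
    phantom_n: int = 3
    phantom_spec: Optional[PhantomSpec] = None
    tumor_fraction: float = 0.5
    patches_per_case: Optional[int] = None


@dataclass(frozen=True)
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    mrf: MRFConfig = field(default_factory=MRFConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    data: DataConfig = field(default_factory=DataConfig)
    noise_in_training: bool = False
    polish_at_inference: bool = False
    noise_at_inference: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "network" in d and isinstance(d["network"], Mapping):
            d["network"] = NetworkConfig(**d["network"])
        if "mrf" in d and isinstance(d["mrf"], Mapping):
            d["mrf"] = MRFConfig(**d["mrf"])
        if "training" in d and isinstance(d["training"], Mapping):
            d["training"] = TrainingConfig(**d["training"])
        if "data" in d and isinstance(d["data"], Mapping):
            data = dict(d["data"])
            if isinstance(data.get("phantom_spec"), Mapping):
                spec = dict(data["phantom_spec"])
                for key in ("grid_shape", "spacing", "tumor_center", "region_radii"):
                    if key in spec and spec[key] is not None:
                        spec[key] = tuple(spec[key])
                data["phantom_spec"] = PhantomSpec(**spec)
            d["data"] = DataConfig(**data)
        return cls(**d)


def load_cases(config: DataConfig, seed: int = 0) -> list[CaseBundle]:
    """Materialize the training cases: from disk if case_dir is set, else phantoms."""
    if config.case_dir is not None:
        case_dir = Path(config.case_dir)
        seg_files = sorted(case_dir.glob("*_seg.nii*"))
        if not seg_files:
            raise FileNotFoundError(f"no *_seg.nii[.gz] files under {case_dir}")
        cases = []
        for seg in seg_files:
            case_id = seg.name.split("_seg")[0]
            paths, mask_path = case_paths(case_dir, case_id)
            cases.append(read_case(paths, mask_path, case_id=case_id))
        return cases
    spec = config.phantom_spec or PhantomSpec()
    return phantom_cohort(config.phantom_n, spec, seed=seed)


def _batches(
    n: int, batch_size: int, max_steps: int, rng: np.random.Generator
):
    """Yield index batches, reshuffling each epoch, for exactly max_steps steps."""
    step = 0
    while step < max_steps:
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            if step >= max_steps:
                return
            yield order[start : start + batch_size]
            step += 1


def train(
    config: RunConfig,
    out_dir: str | Path,
    cases: Optional[Sequence[CaseBundle]] = None,
) -> tuple[Path, list[float]]:
    """Train a fresh network; returns (checkpoint path, per-step loss log)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cases is None:
        cases = load_cases(config.data, seed=config.seed)
    if not cases:
        raise ValueError("empty dataset")
    patch_size = config.network.input_size
    patches = extract_patches_cohort(
        cases,
        size=patch_size,
        tumor_fraction=config.data.tumor_fraction,
        patches_per_case=config.data.patches_per_case,
        seed=config.seed,
    )
    logger.info("training on %d patches from %d cases", len(patches), len(cases))

    net = build_segmenter(config.network, seed=config.seed)
    optimizer = Adam(net.parameters(), lr=config.training.learning_rate)
    rng = np.random.default_rng(config.training.seed)
    noise_rng = np.random.default_rng(config.training.seed + 1)

    images = patches.images.transpose(0, 3, 1, 2)  # NHWC -> NCHW
    masks = patches.masks.astype(np.int64)
    losses: list[float] = []
    for batch in _batches(
        len(patches), config.training.batch_size, config.training.max_steps, rng
    ):
        x = images[batch]
        y = masks[batch]
        logits = net.forward(x, training=True)
        if config.noise_in_training:
            # decoder-output noise injection as a regularizer
            logits = logits + noise_rng.normal(
                0.0, config.mrf.sigma, size=logits.shape
            ).astype(np.float32)
        loss, dlogits = softmax_cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"loss became non-finite at step {len(losses)}: {loss}"
            )
        optimizer.zero_grad()
        net.backward(dlogits)
        optimizer.step()
        losses.append(loss)
        if len(losses) % 25 == 0:
            logger.info("step %d  loss %.4f", len(losses), loss)

    ckpt = save_checkpoint(net, config, out_dir)
    (out_dir / "training_log.json").write_text(json.dumps({"loss": losses}, indent=2))
    return ckpt, losses


def save_checkpoint(net: AttentionUNet, config: RunConfig, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt = out_dir / "checkpoint.npz"
    np.savez(ckpt, **net.state_dict())
    (out_dir / "checkpoint.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str)
    )
    return ckpt


def load_checkpoint(ckpt_path: str | Path, config: RunConfig) -> AttentionUNet:
    net = build_segmenter(config.network, seed=config.seed)
    with np.load(ckpt_path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net


def _polish_slice(
    labels2d: np.ndarray, config: RunConfig
) -> np.ndarray:
    """Per-class bipolar ICM polish of one 2D label slice, priority-recombined."""
    out = np.zeros_like(labels2d)
    for cls in reversed(CLASS_PRIORITY):  # lowest priority first, overwritten later
        binary = labels2d == cls
        x = np.where(binary, 1, -1).astype(np.int8)
        if config.noise_at_inference:
            x = inject_noise(x, config.mrf.sigma, seed=config.mrf.seed)
        polished = icm_denoise(x, config.mrf)
        out[from_bipolar(polished) > 0] = cls
    return out


def predict(
    net: AttentionUNet,
    case: CaseBundle,
    config: RunConfig,
    batch_slices: int = 8,
) -> LabelMask:
    """Segment one case slice-by-slice; output labels shaped like the input."""
    size = config.network.input_size
    h0, w0, depth = case.shape
    vols = {m: zscore_normalize(case.modalities[m]) for m in MODALITIES}
    out = np.zeros(case.shape, dtype=np.int16)
    for start in range(0, depth, batch_slices):
        ks = range(start, min(start + batch_slices, depth))
        x = np.stack(
            [
                _crop_pad_2d(
                    np.stack([vols[m][:, :, k] for m in MODALITIES], axis=-1), size
                )
                for k in ks
            ]
        ).transpose(0, 3, 1, 2)
        probs = net.predict_proba(x)
        labels = probs.argmax(axis=1).astype(np.int16)  # (B, size, size)
        for b, k in enumerate(ks):
            sl = labels[b]
            if config.polish_at_inference:
                sl = _polish_slice(sl, config)
            # undo the center crop/pad back onto the original in-plane grid
            full = np.zeros((h0, w0), dtype=np.int16)
            if h0 >= size:
                hs = (h0 - size) // 2
                src_h, dst_h = slice(0, size), slice(hs, hs + size)
            else:
                hs = (size - h0) // 2
                src_h, dst_h = slice(hs, hs + h0), slice(0, h0)
            if w0 >= size:
                ws = (w0 - size) // 2
                src_w, dst_w = slice(0, size), slice(ws, ws + size)
            else:
                ws = (size - w0) // 2
                src_w, dst_w = slice(ws, ws + w0), slice(0, w0)
            full[dst_h, dst_w] = sl[src_h, src_w]
            out[:, :, k] = full
    return LabelMask(out)


def evaluate_cases(
    preds: Mapping[str, np.ndarray], truths: Mapping[str, np.ndarray]
) -> dict:
    """Per-case and cohort-mean metrics for matched case-id label volumes."""
    unmatched = sorted(set(preds) ^ set(truths))
    if unmatched:
        raise ValueError(f"unmatched case ids: {unmatched}")
    per_case: dict[str, MetricsReport] = {
        cid: evaluate_masks(preds[cid], truths[cid]) for cid in sorted(preds)
    }
    mean_dsc = {
        region: float(np.mean([r.dsc[region] for r in per_case.values()]))
        for region in REGIONS
    }
    return {
        "per_case": {cid: r.as_dict() for cid, r in per_case.items()},
        "mean_dsc": mean_dsc,
    }


def evaluate_dirs(pred_dir: str | Path, truth_dir: str | Path) -> dict:
    """Evaluate ``*_seg.nii[.gz]`` label volumes matched by case id."""
    import nibabel as nib

    def load_dir(d: Path) -> dict[str, np.ndarray]:
        out = {}
        for p in sorted(Path(d).glob("*_seg.nii*")):
            cid = p.name.split("_seg")[0]
            out[cid] = np.round(np.asarray(nib.load(p).get_fdata())).astype(np.int16)
        if not out:
            raise FileNotFoundError(f"no *_seg.nii[.gz] files under {d}")
        return out

    return evaluate_cases(load_dir(Path(pred_dir)), load_dir(Path(truth_dir)))


def report_to_csv(report: dict, path: str | Path) -> Path:
    """Flatten an evaluate() report to one CSV row per case per region."""
    path = Path(path)
    lines = ["case_id,region,dsc,sensitivity,specificity,precision,accuracy"]
    for cid, rep in report["per_case"].items():
        for region in REGIONS:
            vals = [
                rep["dsc"][region],
                rep["sensitivity"][region],
                rep["specificity"][region],
                rep["precision"][region],
                rep["accuracy"][region],
            ]
            cells = ["" if v is None else f"{v:.6f}" for v in vals]
            lines.append(",".join([cid, region, *cells]))
    for region in REGIONS:
        lines.append(f"cohort_mean,{region},{report['mean_dsc'][region]:.6f},,,,")
    path.write_text("\n".join(lines) + "\n")
    return path
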