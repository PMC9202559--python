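# attnseg

Brain-tumor segmentation toolkit built around a VGG19-encoder,
attention-gated U-Net with a 4-class softmax head, followed by optional
Gaussian noise injection and Ising-MRF (ICM) mask polishing — plus a
synthetic multimodal phantom generator so the entire pipeline runs and is
tested at desk scale, with no external data or GPU.

The network is implemented directly in NumPy (explicit forward/backward
passes, Adam), so the package has no deep-learning-framework dependency.

## Components

| module | what it does |
| --- | --- |
| `attnseg.phantom` | synthetic BraTS-like cases: 4 modalities (T1, T1ce, T2, FLAIR) + nested tumor labels (enhancing ⊂ core ⊂ whole) on {0,1,2,3} |
| `attnseg.nifti_io` | NIfTI case read/write, raw label 4→3 remap, z-score normalization over brain voxels, class-balanced 2D patch extraction |
| `attnseg.attention_unet` | VGG19 layer registry + exact parameter counting; spatial-softmax attention gate (standalone op and trainable layer); the full segmenter |
| `attnseg.mrf_polish` | bipolar masks, Gaussian flip noise (`sign(x + N(0,σ²))`), Ising energy `E = −Σ x_p x_q − η Σ x y`, ICM denoising, brute-force exact minimizer |
| `attnseg.metrics` | Dice (both the overlap and the 2TP/(2TP+FN+FP) form), confusion metrics, ET/WT/TC region composites |
| `attnseg.pipeline` / `attnseg.cli` | train / predict / evaluate orchestration, YAML run configs, checkpoints |

Label convention: voxel classes are 1 = necrotic core, 2 = edema,
3 = enhancing; evaluation regions are composites WT = {1,2,3},
TC = {1,3}, ET = {3}.

## CLI

```sh
attnseg phantom --n 5 --out data/ --seed 7 --shape 96 96 16
attnseg patches --case-dir data --case-id phantom-0007-000 --size 96
attnseg build --summary --width-factor 0.25 --input-size 96
attnseg train --out run/ --config run.yaml
attnseg predict --checkpoint run/checkpoint.npz --case-dir data \
    --case-id phantom-0007-000 --out pred/phantom-0007-000_seg.nii.gz
attnseg polish --in pred/mask.nii.gz --out pred/polished.nii.gz --eta 15 --sigma 1.5
attnseg evaluate --pred-dir pred/ --truth-dir data/ --out-csv metrics.csv
```

`attnseg train` with no config trains on three generated phantoms with the
default network (224×224, width 1.0); pass a YAML file mirroring
`attnseg.pipeline.RunConfig` to change the network width, MRF settings,
training schedule, or data source.

## Notes

- Defaults follow the method's stated constants: MRF data weight η = 15,
  noise σ = 1.5 (flip rate Φ(−1/1.5) ≈ 0.2525), 4 classes, 224×224 inputs.
  At η = 15 the data term dominates every possible coupling change, so ICM
  polishing is exactly the identity; use smaller η for visible smoothing.
- `width_factor` scales all channel widths for CPU-scale experiments; the
  acceptance end-to-end test uses width 0.25 at 96×96.
- No pretrained weights ship with the package; `pretrained` options are
  hooks that require a user-supplied weights file.
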