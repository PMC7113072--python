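# histocompress

How much can you compress a digital-pathology image before the algorithms
reading it stop working?

Telepathology — transmitting scanned slides for remote diagnosis — is most
valuable exactly where bandwidth is worst, and whole-slide images are
enormous (a single 40x scan can exceed 5 GB). Lossy compression is the
obvious remedy, but automated analysis pipelines (nuclei segmentation,
tumor-region segmentation, lymphocyte detection, and downstream
nuclear-architecture features used for prognosis) may degrade long before a
human notices. `histocompress` is a desk-scale laboratory for quantifying
that trade-off: it generates seeded synthetic H&E-like scenes with exact
ground truth, compresses them with JPEG or PSNR-targeted JPEG2000, evaluates
a patch classifier trained only on clean images against the compressed
copies, and measures the stability of 77 nuclear-architecture summary
statistics across the compression ladder.

## What it computes

**Compression.** JPEG is driven by its 1–100 quality score. JPEG2000 is
driven to a *target PSNR*: the encoder's compression-ratio parameter is
bisected, measuring round-trip PSNR

```
PSNR = 10 · log10(255² / MSE)   [dB]
```

until the achieved value is within ±0.5 dB of the target (lossless
reversible coding is the 100 dB endpoint). Compression ratio is reported as
compressed bytes over raw bitmap bytes (H·W·3).

**Task performance.** Pixel-level F1 = 2TP/(2TP+FP+FN) for segmentation;
pixel-level ROC AUC (the Mann–Whitney pair statistic) for region
segmentation; detection F1 over one-to-one matched cell centers
(maximum-cardinality, minimum-distance assignment within a radius) for
lymphocyte detection.

**Feature stability.** From each predicted segmentation, 77 first-order
summary statistics in five families — Voronoi cell geometry (12), Delaunay
triangles (8), minimum-spanning-tree edges (4), nuclear morphology and
spacing (27), and cell-cluster subgraphs (26) — are computed; their
per-feature absolute change from the lossless level, normalized to (0,1) by
the per-feature maximum over levels, forms a level × feature stability heat
map.

## Worked example

Run a full sweep — generate scenes, train on clean images, compress the
held-out test images across the JPEG2000 PSNR ladder, score every level:

```python
import histocompress as hc

cfg = hc.SweepConfig(n_train=10, n_test=5, seed=1)
result = hc.run_sweep(cfg, out_dir="demo")
curves, rho = hc.summarize_curves(result)
f1 = curves[curves.metric == "pixel_f1"]
print(f1[["level", "mean_psnr", "mean_ratio", "mean_value", "sd_value"]]
      .sort_values("level", ascending=False).to_string(index=False))
print(f"Spearman(achieved PSNR, ratio) = {rho['jpeg2000']:.3f}")
```

```
 level  mean_psnr  mean_ratio  mean_value  sd_value
 100.0 100.000000    0.686220    0.811300  0.006905
  40.0  39.919056    0.309279    0.811474  0.006814
  35.0  35.084801    0.163002    0.810827  0.006923
  30.0  30.045303    0.066873    0.809558  0.006814
  25.0  24.993194    0.022202    0.806131  0.006894
  22.0  22.064210    0.008571    0.766815  0.007766
  20.0  20.080408    0.004542    0.658950  0.060173
  18.0  18.210771    0.002015    0.285134  0.238777
Spearman(achieved PSNR, ratio) = 0.988
```

Reading the table: `level` is the requested PSNR (100 = lossless),
`mean_psnr` the PSNR the rate search actually achieved, `mean_ratio` the
compressed fraction of raw bytes, and `mean_value` the pixel F1 of the
clean-trained classifier on those compressed test images. Segmentation is
essentially unharmed down to 25 dB — at 30 dB the images occupy only ~7% of
their raw size while F1 is within 0.2% of lossless — then collapses sharply
below 20 dB, the same "cliff" shape reported for real histology. The sweep
also writes `metrics.csv`, per-level feature tables, the stability matrix
(`stability_rel.csv`, `stability.png`) and a manifest under the output
directory.

The same experiment is scriptable from the shell:

```bash
histocompress sweep --out demo --seed 1
histocompress generate --task lymphocyte --n-images 4 --seed 7 --out scenes/
histocompress compress scenes/scene_0000/image.png out.jp2 --target-psnr 30
```

## Layout

- `src/histocompress/synth.py` — seeded synthetic scene generator (nuclei /
  lymphocyte / tumor-region tasks) and lossless scene I/O
- `src/histocompress/codec.py` — JPEG / JPEG2000 encoding, PSNR, rate search
- `src/histocompress/model.py` — patch classifier: sampling, dihedral
  augmentation, training, dense probability maps, peak detection
- `src/histocompress/metrics.py` — pixel F1 / AUC, detection matching
- `src/histocompress/features.py` — 77-statistic nuclear-architecture
  ledger and the stability matrix
- `src/histocompress/pipeline.py` — one-config sweep orchestration
- `docs/methods.md` — models, parameters, and design rationale
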