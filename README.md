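# sttkit

ST-T segment heterogeneity analysis of 12-lead ECGs and derived
vectorcardiograms (VCGs) for myocardial-ischemia screening.

The toolkit implements a complete pipeline for 20 s, 12-lead, 1,000 Hz
records:

1. **Preprocessing** — 0.67 Hz zero-phase Butterworth high-pass (baseline
   drift), 4-level coif4 wavelet denoising with universal soft thresholding
   (high-frequency noise), display-calibration metadata (25 mm/s, 10 mm/mV).
2. **VCG derivation** — fixed 3×8 linear transform from the 8 independent
   leads (I, II, V1–V6) to orthogonal leads X, Y, Z.
3. **Segmentation** — Pan–Tompkins-style R-peak detection, RMS-slope J-point
   plus tangent-method T-offset ST-T delineation, per-lead splicing of the
   per-beat ST-T windows (intervals shared between ECG and VCG).
4. **Features** (17 per record) — sample entropy (m=2, r=0.1) of each of the
   12 ECG and 3 VCG spliced ST-T series; SHI, a Lyapunov-style spatial
   heterogeneity index of the 3-D VCG ST-T trajectory; THI, the RMS of
   per-lead exponential-decay exponents fitted to the VCG ST-T magnitude
   spectra.
5. **Classification** — RBF-kernel SVM under stratified 5-fold CV, with
   single-feature screening (accuracy > 0.6) plus exhaustive subset grid
   search, and a PCA baseline (Minka-MLE dimension). Metrics: accuracy,
   specificity, sensitivity, F1, rank-statistic AUC.

A fully deterministic **synthetic data module** generates labelled
healthy/ischemic cohorts (sum-of-Gaussians PQRST beats; ischemic preset: ST
depression, flattened T wave, beat-to-beat repolarization jitter; optional
baseline drift, 50 Hz powerline and broadband noise) with ground-truth ST-T
annotations, so the whole pipeline is testable offline.

I/O: WFDB format-16 header/signal pairs (self-contained reader/writer),
delimited text matrices, CSV feature tables, JSON evaluation reports.

## CLI

Every stage is independently invocable through the `sttkit` entry point:

```bash
sttkit simulate --n-ischemic 5 --n-healthy 5 --seed 1 --out-dir cohort/
sttkit preprocess cohort/synth-healthy-000.csv --out clean.csv
sttkit derive-vcg clean.csv --out vcg.csv
sttkit segment clean.csv --out beats.csv
sttkit features cohort/*.csv --label healthy --out features.csv
sttkit train features.csv --feature-set ecg_plus_vcg --out report.json
sttkit evaluate features.csv --features S_I,THI,SHI --out eval.json
sttkit run --config config.yaml          # full pipeline on a synthetic cohort
```

`config.yaml` is a strict nested mapping (unknown keys rejected) with
sections `preprocess`, `sampen`, `shi`, `thi`, `model`, `noise`, `simulate`
plus `seed`, `feature_set`, `out_dir`, `log_level`; every field defaults to
the documented dataclass defaults.

## Layout

```
src/sttkit/
  io.py          record containers, WFDB/delimited/feature-table I/O, resampling
  synth.py       synthetic cohort generator with ground-truth ST-T annotations
  preprocess.py  high-pass filtering, wavelet denoising, unit calibration
  _wavelet.py    self-contained orthogonal coif4 DWT
  vcg.py         ECG -> VCG lead transform
  segment.py     R-peak detection, ST-T delineation, splicing
  features.py    sample entropy, SHI, THI, record-level extraction
  model.py       SVM, cross-validation, metrics, feature selection, PCA baseline
  pipeline.py    end-to-end orchestration with strict config + run manifest
  cli.py         click CLI
tests/           pytest suite; tests/_oracles.py holds independent brute-force
                 references; tests/test_acceptance.py mirrors the acceptance
                 criteria one test per criterion
```
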