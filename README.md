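# shadowcyte

Label-free identification and quantification of CD34+ hematopoietic
stem/progenitor cells from lens-free shadow images.

Lens-free shadow imaging records a cell's in-line hologram — a bright
central maximum surrounded by concentric diffraction rings — directly on
a CMOS sensor, with no lenses and no staining. Counting CD34+ cells this
way matters for leukemia diagnosis and stem-cell transplant monitoring,
where the standard method (flow cytometry, FACS) needs fluorescent
labeling, trained operators and expensive hardware. `shadowcyte`
implements the full computational pipeline:

1. **`simshadow`** — synthetic shadow frames with exact ground truth:
   angular-spectrum propagation of circular phase/amplitude objects, two
   class-conditional parameter regimes (CD34+ vs residual mononuclear
   cells), read noise and quantization.
2. **`detect`** — single-cell recognition: global-mean background
   removal, |deviation| > kσ binarization, 3×3 closing, 8-connected
   components with an 8-40 px size filter, 30×30 crops.
3. **`shadowstats`** — radial shadow statistics. The workhorse is
   **PPD**, the intensity drop from the central maximum (CMV) to the
   first dark ring: CD34+ cells concentrate in the 40-60 count band
   (a cell with CMV 156.8 and ring minimum 112.5 has PPD 44.3), while
   residual cells land far above it. CMV/MMD/SMD and Tukey boxplot
   summaries round out the parameter set.
4. **`dataset`** — PPD-gated label assembly, reproducible 8:1:1
   train/val/test splits, bilinear 30→50 px resizing to [0, 1] inputs.
5. **`cnn`** — an AlexNet-style binary classifier in pure NumPy: eight
   3×3 convolutions, five max-pools (50→25→12→6→3→1), three FC layers,
   SELU activations (λ = 1.0507, α = 1.6732), Adam on cross-entropy with
   best-epoch checkpointing, plus Grad-CAM maps.
6. **`quantify`** — per-sample CD34+ percentages and method agreement
   against a reference (FACS-style) measurement: OLS R² and Bland-Altman
   bias with 95% limits of agreement (bias ± 1.96·SD of differences).

## Worked example

```python
import numpy as np
import shadowcyte as sc

# a noiseless sensor frame with 16 planted cells of known class
cfg = sc.OpticalConfig(frame_shape=(384, 384), noise_sigma=0.0)
rng = np.random.default_rng(0)
sites = [(50 + 96 * i, 50 + 96 * j) for i in range(4) for j in range(4)]
cells = []
for k, site in enumerate(sites):
    label = sc.CD34_POS if k % 2 == 0 else sc.RESIDUAL
    radius = 4.3 if label == sc.CD34_POS else 5.9
    cells.append(sc.CellSpec(center=site, radius_um=radius + rng.normal(0, 0.1),
                             class_label=label))
frame = sc.render_frame(cfg, cells)

crops = sc.find_cells(frame.image)
print(f"detected {len(crops)} of {len(cells)} planted cells")
for crop in crops[:4]:
    p = sc.analyze_crop(crop)
    gate = "inside" if 40 <= p.ppd <= 60 else "outside"
    print(f"  cell at {crop.center}: CMV={p.cmv:.1f}  PPD={p.ppd:.1f}  "
          f"MMD={p.mmd} px  ({gate} the 40-60 CD34+ gate)")

report = sc.compare_to_reference(
    [(22.4, 34.4), (85.2, 79.1), (7.7, 7.65), (50.5, 52.83), (40.0, 33.0)]
)
print(f"R^2={report.r_squared:.3f}  bias={report.bias:.2f}  "
      f"LoA=({report.loa_lower:.2f}, {report.loa_upper:.2f})")
```

Output:

```
detected 16 of 16 planted cells
  cell at (50, 50): CMV=126.0  PPD=56.8  MMD=8 px  (inside the 40-60 CD34+ gate)
  cell at (50, 146): CMV=149.0  PPD=95.9  MMD=8 px  (outside the 40-60 CD34+ gate)
  cell at (50, 242): CMV=126.0  PPD=57.2  MMD=8 px  (inside the 40-60 CD34+ gate)
  cell at (50, 338): CMV=149.0  PPD=96.5  MMD=8 px  (outside the 40-60 CD34+ gate)
R^2=0.938  bias=0.24  LoA=(-14.80, 15.27)
```

Every planted cell is recovered, the small (CD34+-like) cells fall
inside the PPD gate while the larger residual-like cells fall outside,
and the agreement report shows the regression and Bland-Altman numbers
for five example sample pairs.

## Command line

A thin CLI wraps the library for shell workflows:

```bash
shadowcyte simulate --config sim.yaml --out frames/ --n-per-class 500 --seed 7
shadowcyte detect   --in frames/ --out crops/ --k-sigma 3.0
shadowcyte stats    --crops crops/ --out params.csv
shadowcyte build    --params labeled.csv --gate 40 60 --split 8 1 1 --seed 7 --out manifest.csv
shadowcyte train    --manifest manifest.csv --crops-root crops/ --config train.yaml --out run/
shadowcyte evaluate --model run/best.pkl --manifest manifest.csv --crops-root crops/ --split test
shadowcyte compare  --pairs pairs.csv --out report/
```

The same commands ingest real 8-bit PNG/TIFF shadow frames, so the
pipeline can be pointed at device data instead of the simulator.

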