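# rimquant

Quantification of indocyanine-green (ICG) fluorescence around colorectal
liver metastases in ex vivo near-infrared images of resected liver slices
("bread loaves"), together with the cohort-level statistics used to study
how chemotherapy, tumor size, superficiality and hepatic steatosis shape
that signal — and a synthetic phantom/cohort generator so every stage can be
exercised and validated without patient data.

ICG is cleared by hepatocytes into bile; around a liver metastasis the
clearance is impaired, so the dye lingers in a peritumoral **rim** while the
healthy parenchyma darkens. On a slice image, with tumor and tissue outlines
annotated, the package measures:

- **MSFI** — mean signal fluorescence intensity: mean over the rim band,
  tissue within 3 mm of the tumor (Euclidean distance between pixel centers);
- **MBFI** — mean background fluorescence intensity: mean over tissue at
  least 5 mm from the tumor (the 3–5 mm shell is an explicit exclusion gap);
- **SBR** = MSFI / MBFI, the contrast a surgeon actually sees;
- **maximum intensity** over the tissue of the analyzed loaf.

The measurement rules mirror the clinical workflow: the loaf with the
largest tumor cross-section (the central slice) is analyzed; backgrounds
contaminated by ICG *stasis* are recomputed over an operator-chosen
representative area or with the stasis region subtracted; lesions with less
than 100 mm² of background tissue pool background pixels from other loaves
of the same specimen, and are excluded when even pooling falls short.
Cohort covariates are derived with standard clinical rules (RECIST 1.1
percentage thresholds, Brunt steatosis bins, a 90-day pretreatment window),
and compared with one-way ANOVA, exact/asymptotic Mann–Whitney U, Pearson
chi-square, Kruskal–Wallis, Spearman correlation, and multiple linear
regression of each fluorescence parameter on pretreatment, superficiality
and tumor size.

## Worked example

Simulate a small study of phantom specimens, quantify it, and run the
statistics:

```sh
python analysis/01_simulate_study.py
python analysis/02_quantify_lesions.py
python analysis/03_cohort_statistics.py
python analysis/04_recovery_checks.py
```

The quantification step prints, for eight simulated specimens (three with a
dim "pretreated" rim):

```
quantified 7/8 specimens
median MSFI / SBR by pretreatment:
            msfi_au    sbr
pretreated
False         0.368  3.618
True          0.182  1.739
```

One specimen is excluded by the 100 mm² background rule (a large tumor in a
small loaf), and the pretreated group shows the planted lower rim signal and
contrast. The recovery step verifies the measurement chain against ground
truth:

```
noise-free phantom MSFI relative error: 0.00e+00
noisy phantom within 4 SE of analytic mean: 25/25 seeds
OLS 2-SE coverage msfi_au:pretreatment: 96.5%
```

The same machinery is scriptable through the `rimquant` CLI
(`rimquant quantify|cohort|simulate|run`), e.g.

```sh
rimquant simulate specimen --seed 3 --n 3 --out sim/
rimquant quantify --images 'sim/*.tif' --annotations 'sim/*.geojson' \
    --cohort cohort.csv --out results/
```

## Library layout

| module | contents |
| --- | --- |
| `rimquant.imaging_io` | TIFF / GeoJSON / CSV readers and writers, pixel-center rasterization |
| `rimquant.bands` | distance field, rim/gap/background masks, MSFI/MBFI/SBR/max, stasis and pooling rules |
| `rimquant.clinical` | RECIST response, Brunt steatosis grade, pretreatment window |
| `rimquant.cohort_stats` | summaries, group tests, correlations, OLS, the full analysis battery |
| `rimquant.synthetic` | phantom and cohort generators with analytic ground truth |
| `rimquant.pipeline` / `rimquant.cli` | orchestration, audit logging, command line |

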