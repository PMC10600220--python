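# tetherscope

Quantitative analysis of **heterochromatin tethering** in rod
photoreceptor nuclei, and of its consequences for chromatin
accessibility.

Mouse rods invert the usual nuclear architecture: heterochromatin sits in
central chromocenters instead of being tethered at the nuclear envelope
by the lamin B receptor (Lbr) or lamin A. Restoring tethering (or its
ectopic return during retinal degeneration) can be read out two ways,
and this package implements both as tested, scriptable pipelines:

1. **Nuclear morphometry** — from single-plane DNA-stain images:
   the *margin-intensity ratio*
   `m = mean intensity in a band at the nuclear margin / mean intensity of the whole nucleus`
   (m > 1: peripheral/tethered heterochromatin; m < 1: inverted),
   chromocenter detection, chromocenter-to-margin distances, perimeter
   and transect intensity profiles, and a replicate-mean one-way ANOVA
   with Tukey's post-hoc test (plus Shapiro-Wilk and Brown-Forsythe
   checks).
2. **Accessibility analysis** — from per-sample narrowPeak calls and
   coverage tracks: merged-region peak intersections (upset logic),
   summit-centered signal matrices, K-means isolation of the
   *tethering-specific cluster* (peaks elevated only in tethered
   samples), gene-proximal annotation with a strand-aware TSS window
   (5 kb upstream to 1 kb downstream), and A/B compartment overlap.

A first-class synthetic-data module generates nuclei images, toy genomes
with planted tethering-specific peaks, negative-binomial count matrices,
and splice-junction tables — all with ground truth — so every stage is
testable without downloads. Expression utilities (count-matrix QC with
the 200/2500/18%/3 thresholds, pseudo-bulk differential expression,
lamin A vs lamin C junction classification) round out the pipeline.

See `docs/methods.md` for the models, parameter defaults, and
limitations.

## Worked example

Simulate an inverted and a tethered cohort (3 biological replicates × 30
cells each), measure every nucleus, and compare groups on replicate
means:

```python
import pandas as pd
from tetherscope.simulate import NucleusSpec, generate_cohort
from tetherscope.morphometry import measure_nucleus, compare_groups

specs = {
    "inverted": NucleusSpec(tether_strength=0.0, seed=1),
    "tethered": NucleusSpec(tether_strength=1.0, seed=2),
}
images, truth = generate_cohort(30, specs, n_replicates=3)
records = pd.DataFrame(
    measure_nucleus(img, *key).as_row() for key, img in images.items()
)
print(records.groupby("group")["margin_ratio"].mean().round(3))
cmp = compare_groups(records, "margin_ratio")
print(f"ANOVA p = {cmp.anova_p:.2e}")
```

prints

```
group
inverted    0.913
tethered    1.478
Name: margin_ratio, dtype: float64
ANOVA p = 1.77e-07
```

— inverted nuclei have a dim margin relative to the whole nucleus
(ratio < 1), tethered nuclei a bright one (ratio > 1), and the
replicate-mean ANOVA across the six biological replicates flags the
difference.

The same end-to-end logic, including the accessibility arm (toy genome →
summit matrices → K-means → proximal annotation), runs from the shell:

```sh
tetherscope demo --seed 0 --out demo_out/
tetherscope simulate genome --out toy/ --seed 0
tetherscope peaks cluster --genome-dir toy/ --out acc/ --seed 0
```

`demo` exits nonzero if any qualitative check fails (tethered > inverted
margin ratio with Tukey p < 0.01; ≥ 90% recovery of planted
tethering-specific peaks with ≤ 5% contamination; recovered proximal
fraction within ±0.02 of the planted 10%). `tetherscope run --config
cfg.yaml` executes multi-stage pipelines with a seeded, checksummed run
manifest.

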