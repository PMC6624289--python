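# nucleoshuttle

Quantitative image analysis of **nucleolar–nucleoplasmic protein
shuttling** from multi-channel immunofluorescence microscopy.

Genome-maintenance proteins such as WRN, XRCC1 and PARP1 reside in
nucleoli of unstressed cells and relocate to the nucleoplasm under
genotoxic stress. This package measures that relocation per cell: the
nuclear area is segmented from a DNA-dye channel (Hoechst), the nucleolar
area from a nucleolar-marker channel (fibrillarin), and for each nucleus
the protein channel is summarized by the ratio of mean fluorescence
intensities

&nbsp;&nbsp;&nbsp;&nbsp;*R* = mean(*I*<sub>protein</sub> | A<sub>nucleoli</sub>) / mean(*I*<sub>protein</sub> | A<sub>nuclei−nucleoli</sub>)

displayed as *R* − 1, so 0 is a homogeneous distribution, positive values
nucleolar accumulation, negative values nucleolar depletion. On top of the
per-cell statistic the package provides the three-category (strong /
medium / without) classification, replicate-hierarchical aggregation
(mean ± SEM across independent experiments), chi-square and two-way-ANOVA
testing with star annotation, release/recovery kinetics detection, and the
H₂O₂-scavenging-activity calculation for the accompanying plate assay.

Because raw microscopy for this assay is typically not deposited, the
package ships a first-class **synthetic-field generator**: fields of
non-overlapping elliptical nuclei, each with 1–5 circular nucleoli, a
protein channel with a controllable ground-truth enrichment factor *e*,
and Poisson–Gaussian noise — so every pipeline stage is verifiable against
known truth. See `docs/methods.md` for the models and defaults.

Intended users: cell biologists and image analysts quantifying subnuclear
protein redistribution in fixed-cell fluorescence data, and anyone needing
a tested reference implementation of the compartment-ratio statistic.

## Worked example

```python
import numpy as np
from nucleoshuttle import (
    SyntheticSpec, generate_field, segment_nuclei, segment_nucleoli,
    quantify_field, mask_iou,
)

spec = SyntheticSpec(n_nuclei=6, enrichment_factor_e=3.0, seed=42)
field, truth = generate_field(spec)

nuclei = segment_nuclei(field.channel("nuclear_dye"))
nucleoli = segment_nucleoli(field.channel("nucleolar_marker"), nuclei)
print(f"segmented {nuclei.n_labels} nuclei, {nucleoli.n_labels} nucleoli")
print(f"nucleus mask IoU vs truth: {mask_iou(nuclei, truth.nucleus_mask).mean_iou:.3f}")

records = quantify_field(field, nuclei, nucleoli)
for rec in records[:3]:
    print(f"nucleus {rec.nucleus_label}: R = {rec.ratio:.3f}, "
          f"R-1 = {rec.displayed_ratio:.3f}, category = {rec.category}")
ratios = [r.ratio for r in records if r.ratio is not None]
print(f"mean ratio over {len(ratios)} cells: {np.mean(ratios):.3f} (true e = 3.0)")
```

prints

```
segmented 6 nuclei, 20 nucleoli
nucleus mask IoU vs truth: 0.996
nucleus 1: R = 2.939, R-1 = 1.939, category = strong
nucleus 2: R = 2.965, R-1 = 1.965, category = strong
nucleus 3: R = 2.968, R-1 = 1.968, category = strong
mean ratio over 6 cells: 2.936 (true e = 3.0)
```

The field was simulated with a true nucleolar enrichment of *e* = 3 under
default shot + read noise; segmentation recovers the nuclei at IoU ≈ 1 and
the per-cell ratios recover *e* to within a few percent, each cell scoring
"strong" (R > 1 + δ, δ = 0.1). On real data, replace `generate_field` with
`read_field` on your TIFFs and carry condition metadata
(genotype / treatment / timepoint / replicate) in `FieldMetadata`; then
feed the records to `aggregate`, `chisq_test` / `anova_two_way` and
`kinetics_summary`.

## Command line

Every stage is also a subcommand:

```bash
nucleoshuttle simulate  --out sim --n-fields 3 --seed 1 -e 3.0
nucleoshuttle segment   --field sim/field000.tif --out sim/field000
nucleoshuttle quantify  --field sim/field000.tif \
    --nuclei sim/field000_nuclei.tif --nucleoli sim/field000_nucleoli.tif \
    --out records.csv --replicate-id rep1
nucleoshuttle analyze   --records records.csv --design genotype,timepoint --out results/
nucleoshuttle scavenging --in plate.csv --out activity.csv
nucleoshuttle run       --config study.yaml   # all-in-one, deterministic per seed
```

`run` writes `records.csv`, `summary.csv`, `tests.csv`, `kinetics.csv` and
a `manifest.json` with the config echo, seed and SHA-256 checksums;
rerunning the same config reproduces byte-identical outputs.

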