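# vesselquant

Quantification of vessel-wall components in Masson's-trichrome-stained
histological images, with permutation-test statistics for comparing vein
groups.

Masson's trichrome renders smooth-muscle fibers (SMF) in reddish tones and
the collagen/elastin extracellular matrix (ECM) in blue/green.  In chronic
venous disease the balance between the two changes, but manual grading of
stained sections is subjective and hard to compare across studies.
`vesselquant` measures that balance objectively, in two stages:

1. **Pre-processing** — the RGB image is converted to CIELab; dark tissue
   folds (L\* below half the first predominant histogram peak) and blood
   residue (a spherical color mask in Lab) are removed; the lightness is
   contrast-stretched by `round(100·(L−Lmin)/(Lmax−Lmin))`; Otsu's method
   binarizes the result and a two-pass DBSCAN cleanup removes dust specks
   and fills pinholes, yielding the vessel-wall mask and its area
   `A_TOT` (in pixels).
2. **Feature extraction** — everything outside the wall is painted white
   and the image is clustered by k-means (k = 3, Euclidean distance in
   Lab, best of several random restarts by the cost
   `J = Σ_j Σ_i distance(px_ij, centroid_j)`) into SMF, ECM and
   background.  The normalized areas are `Ā_SMF = A_SMF / A_TOT` and
   `Ā_ECM = A_ECM / A_TOT`.

Group differences in the normalized areas are assessed by **permutation
tests**: the two groups are pooled and resampled without replacement m
times; with b resamples at least as extreme as the observed statistic the
p-value is `p = (b+1)/(m+1)`, never exactly zero, with a binomial
confidence interval for the Monte-Carlo uncertainty.  These tests make no
normality or equal-variance assumptions, which matters at the small sample
sizes typical of histological studies.

Because no public database of stained vein sections exists, the package
ships a synthetic generator (`vesselquant.synthetic`) that renders
annular vessel images with known per-pixel ground truth — wall, SMF/ECM
blotches, folds, blood blobs, dust — so the whole pipeline is testable by
parameter recovery.

## Worked example

```python
import dataclasses, json
from vesselquant import VesselSpec, generate_vessel_image, process_image

spec = VesselSpec(smf_fraction=0.4, seed=7)   # 160x160 synthetic vessel
rgb, truth = generate_vessel_image(spec)
rec = process_image(rgb, sample_id="demo", seed=1)
print(json.dumps(dataclasses.asdict(rec), indent=2))
```

prints

```json
{
  "sample_id": "demo",
  "a_smf": 3446,
  "a_ecm": 5181,
  "a_tot": 8666,
  "ratio_SMF": 0.3976459727671359,
  "ratio_ECM": 0.5978536810523887,
  "fold_t": 29.5,
  "otsu_T": 0.492156862745098,
  "seed": 1,
  "config_hash": "4c510cf75b4a",
  "version": "0.1.0"
}
```

(abridged): the wall covers 8,666 pixels, of which 3,446 clustered as SMF,
giving `Ā_SMF ≈ 0.398` against a generator ground truth of 0.399; `fold_t`
and `otsu_T` are the two thresholds derived for this image.  Comparing two
small groups of such ratios:

```python
from vesselquant import PermutationConfig, permutation_test
res = permutation_test(
    [0.42, 0.38, 0.45, 0.35, 0.40, 0.47],
    [0.61, 0.58, 0.66, 0.57, 0.63, 0.60, 0.59, 0.64],
    PermutationConfig(m=100_000, seed=1),
)
print(res.p_value, res.ci)
# 0.00033999660003399966 (0.000226, 0.000454)
```

The observed mean difference of −0.198 is matched or exceeded by only 33
of 100,000 resamples, so the groups differ clearly.

## Command line

```sh
vesselquant synth --out imgs --n 4 --smf-fraction 0.4 --seed 0
vesselquant process imgs/synthetic_000.png --seed 1
vesselquant batch manifest.csv --out results --seed 0     # manifest: sample_id,group,path
vesselquant stats ratios.csv --out stats --m 100000 --workers 4
vesselquant synth-cohort --out cohort.csv --n 6,22,20
```

`batch` writes `records.csv` (one row per image with areas, ratios,
thresholds, seed and config hash) plus a pairwise p-value report with b,
m, seed and confidence interval per cell.

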