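# iristex

Characterization of iris surface features from photograph annotations, and
the statistics used to compare them across populations.

The package covers the full pipeline around a circle-based annotation
record of a photographed iris:

- **annotation model** (`iristex.annotation`) — typed, validated domain
  objects (best-fit circles, crypt/spot marks, furrow/nodule observations,
  feature grades, participant records) with JSON / JSON-lines and CSV
  interchange. Circles need not be concentric; nesting is validated by ray
  sampling.
- **geometry** (`iristex.geometry`) — ray–circle intersection, pupillary /
  ciliary zone classification, anatomical quadrant assignment, ciliary
  extension fraction, automatic large/small crypt classification (strict
  "more than 50%" rule), angular arc unions with the strict "more than
  180°" rule, and iris width.
- **grading** (`iristex.grading`) — the five ordinal/binary feature grades
  (crypts 1–4, furrows 1–3, nodules 1–3, pigment spots 1–3 collapsed from a
  raw 1–4 scale, melanosis 0/1) and the per-iris characterization record.
- **statistics** (`iristex.stats`) — Goodman–Kruskal gamma with a
  calibrated independence test, linear weighted kappa, Pearson chi-square
  homogeneity, grouped-count two-sample t (pooled/Welch), Bonferroni
  thresholds, one-way ANOVA, tabulation and quadrant prevalence. All
  statistics are computed from first principles; scipy supplies only the
  reference distributions.
- **association** (`iristex.association`) — allele frequencies,
  Hardy–Weinberg chi-square, genotype dummy coding with a minimum-class
  rule, maximum-likelihood proportional-odds ordinal regression (authored,
  not wrapped: analytic gradients, monotone threshold reparameterization,
  Wald tests, Nagelkerke R², deviance/Pearson goodness of fit) and a
  likelihood-ratio parallel-lines check. Odds ratios read as the odds of a
  *higher* grade.
- **simulation** (`iristex.simulate`) — seeded generators: cohorts with
  Hardy–Weinberg genotypes and a cumulative-logit genotype→crypt-grade
  link, annotations that round-trip through `characterize` for any target
  grade vector, and a confusable re-rater for reliability studies.
- **fixtures & reports** (`iristex.fixtures`, `iristex.reports`) — the
  published category-count, descriptive and odds-ratio tables packaged with
  provenance strings, and a reproduction report comparing recomputed
  statistics against the printed ones at printed precision.

## CLI

```sh
iristex reproduce                      # recompute printed statistics from packaged tables
iristex simulate --seed 1 --cohort-out cohort.csv
iristex simulate --seed 1 --annotations-out grid.jsonl
iristex validate grid.jsonl
iristex grade grid.jsonl --out graded.csv
iristex stats cohort.csv
iristex assoc cohort.csv --marker rs10235789 --population European
```

## Annotation schema (JSON, one object per iris)

```json
{
  "id": "iris-1", "eye_side": "right", "mirrored": false, "obstructed": false,
  "iris_centre": {"x": 600.0, "y": 400.0},
  "pupil_centre": {"x": 603.0, "y": 398.0},
  "pupil_circle":      {"centre": {"x": 603.0, "y": 398.0}, "radius": 45.0},
  "collarette_circle": {"centre": {"x": 596.0, "y": 404.0}, "radius": 95.0},
  "sclera_circle":     {"centre": {"x": 601.0, "y": 399.0}, "radius": 195.0},
  "crypts": [{"tip": {"x": 700.0, "y": 350.0}, "from_collarette": true}],
  "spots":  [{"x": 650.0, "y": 420.0}],
  "furrows": {"present": true, "over_180": false, "quadrants": [false, false, true, false]},
  "nodules": {"present": false, "over_180": false, "quadrants": [false, false, false, false]},
  "melanosis": false,
  "self_colour": 3
}
```

Coordinates are image pixels (origin top-left, y downward). For an
unmirrored right-eye photograph, nasal is +x and superior is −y; quadrant 1
is upper-nasal, 2 lower-nasal, 3 lower-temporal, 4 upper-temporal.

Cohort CSVs have a fixed header (`id, population, sex, age_years,
iris_width_px, crypt_grade, furrow_grade, nodule_grade, spot_grade,
spot_raw_grade, melanosis, colour`, per-feature quadrant flags, exclusion
columns) followed by one column per genetic marker with derived-allele
copies 0/1/2 (empty = missing).
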