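# topoliver

Topological texture analysis of masked liver MRI slices for predicting
1-year hepatic decompensation in primary sclerosing cholangitis (PSC).

Chronic cholestatic liver disease remodels hepatic parenchyma — fibrosis,
nodularity, perfusion heterogeneity — in ways that change the *shape* of the
intensity landscape of a contrast-enhanced T1-weighted slice before any single
radiological sign is obvious. This package quantifies that shape with cubical
persistent homology and turns it into a fixed-length feature vector for a
simple, auditable classifier. It is written for imaging researchers who want
a transparent, fully seeded reference implementation of the approach, together
with a synthetic phantom cohort that reproduces the qualitative topological
contrast between outcome groups (patient images cannot be shared).

## Method

For each subject with a grayscale slice and a co-registered binary liver mask:

1. **Patching** — the 25 non-overlapping windows (default 32 px for clinical
   matrices, 16 px for the 128-px phantoms) with the highest liver fraction,
   each required to be ≥ 80% liver, are tiled row-major into one 5×5 mosaic.
2. **Cubical persistence** — the mosaic becomes a sublevel-set filtered
   cubical complex (T-construction: pixels are 2-cells with their own
   intensity; every face carries the minimum over its incident pixels, so the
   sublevel set at ε is the union of closed pixels ≤ ε, with 8-connected
   components). Boundary-matrix reduction over **Z**/2 yields H₀ (components)
   and H₁ (loops) intervals (b, d); Betti curves b₀(ε), b₁(ε) and barcodes are
   derived views. An independent union-find + Euler-characteristic oracle
   (b₁ = b₀ − χ, χ = V − E + F) cross-checks every Betti curve.
3. **Persistence images** — intervals map to (birth, persistence) points and
   are rasterized on a 20×20 grid: each point contributes an isotropic
   Gaussian (σ = 0.05 × intensity range) weighted by w(p) = p / p_max, with
   pixel values computed as exact integrated Gaussian mass (CDF products).
   Grid bounds, σ and p_max are fitted on training subjects only.
4. **LBP features** — uniform local binary patterns (P=8, R=1, u2 mapping,
   59 bins) of the H₀ and H₁ persistence images, concatenated (118 features).
5. **Classification** — a fully grown CART decision tree (gini, no pruning,
   `random_state=33`) under stratified 5-fold cross-validation; balanced
   accuracy, weighted F1, AUROC (Mann–Whitney rank formulation, ties ½) and
   average precision, aggregated as median ± MAD across folds.

The phantom generator (`topoliver.phantom`) supplies seeded two-class
cohorts: elliptical liver masks textured with dark disks (H₀ control) and
dark annuli (each contributes exactly one H₁ loop with persistence equal to
its contrast) plus correlated Gaussian noise. The decompensating profile has
many small, low-contrast, short-lived features and a narrow Betti range; the
non-decompensating profile fewer, larger, long-lived features and a wide
Betti range.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_cross_validate.py
python analysis/04_reported_tables.py
```

`02` prints the per-class topological contrast of the simulated cohort
(means over 30 subjects per class):

```
            max_b0    max_b1  mean_h1_persistence
decomp     57.0000   43.6333               0.0154
no_decomp  77.3333  123.1667               0.0237
```

— the decompensating class stays in a narrower Betti range and its loops are
markedly shorter-lived, the designed contrast. `03` then cross-validates the
tree on LBP features of the persistence images:

```
 balanced_accuracy: folds 1.00  1.00  1.00  1.00  1.00 -> 1.00 (± 0.00)
             auroc: folds 1.00  1.00  1.00  1.00  1.00 -> 1.00 (± 0.00)
```

(the default phantom classes are well separated; see `docs/methods.md` for
what this does and does not demonstrate about clinical data). `04` recomputes
the published derivation-cohort arithmetic: median balanced accuracy 0.80,
median average precision 0.74, median AUROC 0.80, cohort composition
21/54 females = 38.9% and 49/54 IBD = 90.7%, and the patient flow
590 − 298 = 292.

The same stages are available as a CLI (`topoliver synth | extract |
homology | featurize | train | evaluate | run-all`), e.g.

```bash
topoliver run-all --n-per-class 10 --seed 3 --out scratch/demo
```

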