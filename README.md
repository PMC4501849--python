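# lineatime

Division-timing statistics for *C. elegans* embryo lineage recordings:
timing extraction from curated 4D nuclei-tracking tables, the
**asynchrony of division between sister cells (ADS)** statistic, wild-type
reference construction, RNAi-screen hit calling, variance-buffering
detection, and embryo spatial statistics — together with a seeded synthetic
embryo-recording generator used to validate every step.

## The problem

During the proliferative stage of *C. elegans* embryogenesis, sister cells
born from the same division often divide at markedly different times. This
asynchrony (ADS) is reproducible across embryos and is under genetic
control. High-content screens perturb one gene at a time, record the embryo
in 3D time-lapse at 1.5-minute intervals, reconstruct the invariant
Sulston-named lineage up to the ~350-cell stage, and ask which genes
collapse the asynchrony of specific sister pairs, which inflate the
variability of division timing (a "buffering"/capacitor phenotype), and
which displace cells or rotate division axes.

This package is for computational biologists working with automated
lineaging output (AceTree/StarryNite-style tables: one row per cell per
frame with name, position and optional marker intensity). It implements
the full statistical pipeline downstream of image curation.

## The statistics

For a cell *c* born at frame *b(c)* whose daughters appear at frame *d(c)*,
the cycle length is *T(c) = (d(c) − b(c)) · Δt* with *Δt* = 1.5 min.
For a parent *p* with daughters *d₁, d₂* (born together),

&nbsp;&nbsp;&nbsp;&nbsp;ADS(p) = |T(d₁) − T(d₂)|.

Cells that had not divided by the analysis cutoff (the ~350-cell frame),
died, were not observed from birth, or belong to the first two division
rounds (AB, P1, ABa, ABp, EMS, P2) are censored.

* **Wild-type reference** — per pair, ADS across the cohort is modelled as
  N(μ, σ²); normality is assessed with D'Agostino's K² = z(√b₁)² + z(b₂)²
  (χ², 2 df) and recorded. Pairs with μ > 5 min are monitored.
* **Hit calling** — a replicate flags pair *p* at level α when its ADS is
  uncensored, ≤ (1 − 0.5)·μ_WT, below μ_WT, and in the two-sided normal
  tail with p < α; a gene is a hit at α when ≥ 2 replicates flag. Embryos
  failing developmental-speed QC (< 300 cells at the last editable frame,
  or < 350 cells by frame 240 when curation reaches that far) are excluded.
* **Buffering** — per generation of the AB sublineage, the variance of
  per-cell deviations from the wild-type mean is compared between perturbed
  and wild-type embryos with a one-sided F-test; a gene with min-p < 0.01
  is flagged.
* **Spatial statistics** — embryos are registered on axes defined at the
  last four-cell frame (ABa→P2 = A-P; ABp→EMS, orthogonalized, = L-R) and
  scaled to [−1, 1]; positional deviation is the distance to the wild-type
  centroid under a normal model of wild-type distances; division angles
  against the AP-LR / AP-DV / LR-DV planes are Box–Cox transformed (λ by
  MLE), de-noised at 3 SD, and tested the same way.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic screen
(20 wild-type embryos, 8 pseudo-genes × 3 replicates; the raw recordings go
to `scratch/`, summary tables to `results/`):

```bash
python analysis/01_simulate_screen.py
python analysis/02_wildtype_reference.py
python analysis/03_screen_hits.py
python analysis/04_spatial_statistics.py
```

`02_wildtype_reference.py` prints, for the wild-type cohort:

```
quantified 345 cell cycle lengths per embryo; 183 sister pairs with >= 8 uncensored values
monitored pairs (mean ADS > 5 min): ['ABal', 'ABala', 'ABar', 'ABpl', 'ABplp', 'ABpr', 'C', 'Ca', 'E', 'MS', 'MSa', 'P3']
between-embryo Pearson r: median 0.951, range 0.942-0.961
mean cycle-length SD by generation (min): g3: 0.93, g4: 1.11, g5: 1.15, g6: 1.28, g7: 1.34, g8: 1.42
```

i.e. the 12 sister pairs simulated as asynchronous are exactly the ones the
5-minute threshold selects, embryos are highly reproducible, and timing
variability grows with generation. `03_screen_hits.py` then prints the
gene × pair hit matrix:

```
               ABal ABala  ABar  ABpl ABplp  ABpr     C    Ca     E    MS   MSa    P3
ads-collapse   0.01  0.01  0.01  0.01  0.01  0.01  0.01  0.01  0.01  0.01  0.01  0.01
ads-partial          0.01                                                        0.01
arrest
...
```

The asynchrony-collapsing gene is recovered on every monitored pair, the
partial perturbation only on its two true target pairs (ABala, P3), the
arrested gene is reported `unscreenable` after QC, and the null gene is
clean. `04_spatial_statistics.py` reports that all three replicates of the
mispositioned gene shift ABala away from the wild-type centroid
(median p ≈ 1e-5) while the null gene does not.

The same pipeline runs from the shell on any manifest of nuclei tables:

```bash
lineatime simulate --out data/ --n-wildtype 20 --seed 7
lineatime all --manifest data/manifest.tsv --out reports/ --seed 7
```

## Layout

```
src/lineatime/        library: nomenclature, model, io, timing, reference,
                      screen, spatial, simulate, pipeline, cli
analysis/             numbered narrative drivers over the library
tests/                pytest suite (unit, property, acceptance)
scripts/acceptance.py end-to-end verification quantities
docs/methods.md       models, assumptions, parameter choices, limitations
```
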