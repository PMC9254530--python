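# Methods

## Containers and conventions

PET volumes are 3D grids of body-weight-normalised SUV (dimensionless,
non-negative) with physical voxel spacing in mm; masks are binary grids
voxel-aligned to their volume. Voxel indices are 0-based; voxel centres
sit at `index * spacing`; world coordinates follow the NIfTI affine. A
mask whose shape or spacing differs from its volume (spacing tolerance
1e-3 mm) is an error — nothing is ever silently resampled, because
resampling policy is site-specific and changes the statistics being
measured.

SUV conversion: `SUV = C / (D · 2^(−Δt/T½) / m)` with concentration `C`
in kBq/mL, injected dose `D` in kBq, body mass `m` in grams (1 mL ≡ 1 g)
and Δt the injection-to-scan interval. The ¹⁸F half-life is fixed at
109.77 min. Body-weight normalisation (not lean-body-mass) is used
throughout, matching paediatric weight-based dosing practice. Both
timestamps are carried in the metadata, so either decay-correction
convention (to scan start or to injection) is computable; the package
decays dose to scan time.

## Segmentation

The manual total-lesion outline is an input. The 40 %-of-SUVmax region
is derived from it: voxels of the manual mask with
`SUV ≥ fraction × SUVmax`, SUVmax taken over the manual mask.
Documented tie rules, chosen where the field's descriptions are silent:

* the comparison is inclusive (`≥`), so the maximal voxel always
  survives and the region is never empty;
* all supra-threshold voxels are kept — no largest-component pruning
  (a heterogeneous lesion may legitimately split into islands);
* the threshold is never applied outside the manual mask, which would
  capture physiologic uptake elsewhere in the field of view.

Masks are nested in the threshold fraction: a larger fraction always
yields a subset.

## Metabolic parameters

Over a region: SUVmax and SUVmean are the voxel maximum and mean;
`MTV = voxel count × voxel volume` (mL); `TLG = MTV × SUVmean` **of the
same region** (each delineation uses its own mean — this is the
convention under which reported MTV/TLG/AUC-CSH triples are mutually
consistent). SUVpeak is the maximal average SUV in a 1.0 cm³ sphere
(radius 6.2035 mm) whose centre ranges over the region's voxels; sphere
membership is voxel-centre-in-sphere with 0/1 weights (deterministic and
oracle-checkable: on a 4 mm isotropic grid the sphere holds exactly 19
voxel centres). By default the sphere may average voxels outside the
mask — the common fixed-volume definition; `restrict_to_mask=True`
confines it to the region, since which behaviour the clinical software
used is generally unstated. At the image border the sphere is clipped
and the average runs over in-grid voxels.

## The heterogeneity index

`CSH(t)` is the fraction of region volume with `SUV ≥ t × SUVmax_ref`
on a uniform grid of `n_bins` + 1 thresholds (default 1000, inclusive
comparison matching the segmentation tie rule). Two AUC values are
always reported:

* `auc_trapezoid` — trapezoidal integration of the binned curve;
* `auc_exact` — the bin-free identity `SUVmean_region / SUVmax_ref`,
  exact because `∫₀¹ P(SUV ≥ t·M) dt = E[SUV]/M` whenever
  `0 ≤ SUV ≤ M`.

They agree to `O(1/n_bins)` (enforced at 2/n_bins); since the binning
used by any given clinical implementation is unknown, reporting both
bounds the discrepancy. The binned value can shift by up to one bin
width under SUV rescaling when a voxel value falls exactly on a bin
edge; the identity value is exactly invariant under rescaling and voxel
permutation.

For the 40 % region the threshold reference is the **total-lesion**
SUVmax (shared reference). The region contains the maximal voxel, so
this equals the region-local maximum numerically, but the shared
convention is what makes the two indices directly comparable and yields
the subset-mean inequality `AUC-CSH₄₀% ≥ AUC-CSH_total` for every
lesion.

## Digital phantoms

Spherical lesions (radius R, true peak S) on a background grid, with
five radial SUV profiles and closed-form truth for SUVmean, MTV, TLG,
AUC-CSH and (where the profile is radially non-increasing) SUVpeak:

| profile | SUV(r) | AUC-CSH |
|---|---|---|
| homogeneous | S | 1 |
| two_level | S in a core of volume fraction w, `low·S` outside | w + (1−w)·low |
| radial_linear | S(1 − r/R) | 1/4 |
| necrotic_core | `low·S` in a core of radius fraction c, S outside | 1 − c³(1 − low) |
| uniform_histogram | S(1 − (r/R)³), exactly uniform SUV histogram | 1/2 |

Defaults: 64³ grid at 2 mm, R = 25 mm, S = 5, centre on an exact voxel
so the profile apex is sampled (otherwise the discretised SUVmax
underestimates S and biases the index upward). Voxel membership is
voxel-centre-inside-sphere with no partial-volume weighting — simple,
exact and testable. Noise, when requested, is additive Gaussian on the
tumour voxels clipped at zero, the simplest stand-in for reconstruction
noise; analytic truth always refers to the noise-free continuous
profile. The phantoms emulate uptake *distributions*, not PET physics:
no point-spread blurring, scatter, attenuation artefacts or
partial-volume effects, so passing tests certify the numerics of the
extraction, not robustness to scanner effects.

At 2 mm voxels the discretised index lands within 0.01 of the
closed-form value on all profiles, and the error shrinks at 1 mm (both
tested). The necrotic-core SUVpeak truth is omitted: the optimal sphere
centre lies in the shell and has no simple closed form.

## Simulated cohorts

One row per patient. Defaults reproduce a 38-patient pretreatment
neuroblastoma series: age 3.636 ± 2.166 y, 14/38 male, 34/38 abdominal
primaries, INSS stages (2, 1, 6, 29)/38, COG risk (2, 14, 22)/38, and a
19/38 event rate. AUC-CSH_total is drawn from a two-component truncated
normal mixture matching the event / non-event subgroup statistics
(0.410 ± 0.062 vs 0.515 ± 0.101), with AUC-CSH₄₀% from its own group
components (0.541 ± 0.039 / 0.581 ± 0.049) Gaussian-copula-correlated
at 0.63. The remaining imaging features are internally consistent with
the CSH identity (`SUVmean = AUC-CSH × SUVmax`, `TLG = MTV × SUVmean`
per delineation) around lognormal MTV/SUVmax marginals at the cohort's
reported medians. Serum markers (NSE, LDH, PHOX2B) are lognormal on
laboratory-typical scales; bone-marrow-involvement prevalence has no
reported anchor and defaults to 0.5 (configurable).

Survival is exponential proportional hazards on
`η = Σ log_hr[k]·x_k` — Cox, being semi-parametric, is correctly
specified under this generator and planted hazard ratios have
closed-form truth for recovery tests. Default planted effects are a
bone-marrow-involvement HR of 4.677 and an AUC-CSH_total HR of 0.005
per unit of the index. Censoring is uniform on (0, 33.4] months (the
series' maximum follow-up). The baseline hazard is calibrated by root
finding so the expected event fraction hits the 19/38 target under the
spec's covariate distributions; the calibration uses a fixed internal
reference draw, so it depends only on the cohort parameters, never on
the cohort seed.

A modelling consequence worth knowing: the mixture is indexed by a
*latent* group label, while the realised event indicator emerges from
the hazard model. The realised event/non-event separation of the index
is therefore attenuated relative to the component means — the generator
reproduces the planted component statistics exactly and the subgroup
contrast approximately.

## Cohort statistics

* **Subgroup comparison** — Welch's t-test when both groups pass
  Shapiro–Wilk at α = 0.05, Mann–Whitney otherwise (reported styles in
  the field mix mean ± sd and median/IQR without stating a rule; the
  screen decides per column). COG risk is binarised high vs
  low/intermediate.
* **Cox regression** — `lifelines` partial likelihood, Breslow ties
  (the SPSS default, for comparability with clinical reports).
  Backward-stepwise elimination drops the largest Wald p above 0.10
  (SPSS backward-Wald default; configurable), recording the
  elimination path; threshold 1 retains all candidates, threshold 0
  eliminates down to the empty model. Non-convergence / separation is
  raised as a diagnostic error, not a silent crash. AUC-CSH enters on
  its raw (0, 1] scale, so its hazard ratios are "per unit index" and
  legitimately tiny with near-zero confidence bounds.
* **ROC cutoff** — Youden's J over observed feature values, orientation
  chosen from the data, ties resolved to the midpoint of the maximising
  region (the gap midpoint under perfect separation).
* **Kaplan–Meier / log-rank** — product-limit curves per group and the
  k-group log-rank test; all-censored cohorts report an undefined p
  rather than failing. The combined stratification assigns Group I
  (index above cutoff, no marrow involvement), Group III (both risk
  factors) and Group II (exactly one — the "or" must be exclusive for
  the groups to partition the cohort).
* **Baseline table** — continuous variables as mean ± sd or median
  (IQR) per the same normality screen with rank-sum p; categoricals as
  n (%) with chi-square p. No multiple-testing correction is applied
  anywhere; all p-values are raw.
* Event-free survival is time to first relapse/progression/death,
  censored at last follow-up. Rows with missing model variables are
  dropped from a fit.

## Validation problem sizes

Chosen so each check estimates what it claims with sensible Monte-Carlo
margins: hazard-ratio recovery on 10⁴ patients (±10 %); type-I error of
log-rank and subgroup tests over 1000 null replicates of the default
cohort; the subset-mean inequality over a 200-phantom random sweep;
binned-vs-exact oracle agreement (10⁵ bins, 1e-6) on 50 random lesions
of 100–500 voxels — lesions of only a few voxels intrinsically carry
binning jitter of order `Δt/√(12n)`, which is why the sweep uses
realistic delineation sizes; Youden-cutoff stability over 100 seeds of
500-patient draws from the planted index mixture, where the cutoff
estimates the population density crossing (~0.47) rather than
small-cohort sampling noise.

## Known limitations

* No PET physics: phantom validation certifies extraction numerics, not
  behaviour under scanner blur or motion.
* Single-lesion analysis; no metastatic-lesion or multi-lesion support.
* The cohort generator's subgroup contrast is attenuated (latent-label
  mixture vs realised events, above).
* The exact binning and SUVpeak sphere convention of clinical software
  vary; both are parameterised, and the bin-free identity value is the
  recommended primary output.
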