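# Methods

This note records the scientific and numerical choices behind each stage
of the pipeline, in the package's own terms: what is modeled, which
conventions are fixed where several exist, and what the synthetic cohort
can and cannot show.

## Synthetic phantom cohort

The phantom stands in for a patient cohort and defines the study
conditions for every downstream test.

**Geometry.** Brain: an axis-aligned ellipsoid with semi-axes 0.46 × the
grid extent. CE core: a sphere of default radius 7 mm placed 5 mm off
the midline (axis 0), with per-subject radius jitter ±15%. Progression
region: a spherical-cap shell of default thickness 8 mm abutting the
core — the radial band (R, R + 8 mm] restricted to a cone of 75°
half-angle around a per-subject random direction — minus the core, so
disjointness from the CE lesion holds by construction. Real lesions are
irregular; a sphere plus cap is used because no tested formula depends
on lesion shape, and the analytic geometry makes exhaustive voxel-count
oracles possible. A configuration whose core or cap leaves the brain is
rejected as a geometry error rather than silently clipped.

**Intensity model.** Per modality: baseline + shift·1[progression]
+ 1.5·shift·1[CE core] + noise. The CE multiplier is a fixed convention
so the core is visible in CE-vs-peritumoral summaries; nothing tested
depends on it. Noise is white Gaussian smoothed to a 2 mm FWHM
(re-normalized to the configured sd), mimicking the spatial correlation
of MR texture. Baselines sit at plausible clinical scales (ADC ≈ 1.2,
FA ≈ 0.40, FLAIR ≈ 110 a.u. …) but are arbitrary units: only the signs
and signal-to-noise of the shifts matter downstream. Default shifts are
+0.8 × noise sd for FLAIR, T1C and rCBV, −0.8 × sd for ADC, DTI-p and
FA, and exactly 0 for DTI-q — the sign pattern of the group contrasts
the method is designed to detect. The magnitude 0.8 sd is a free
parameter (only ROI-level significance, not per-voxel effect sizes, is
reported for the real cohort); it was chosen once as "strong effects":
large enough for parameter recovery at desk scale, small enough that a
single modality voxel is far from separable on its own.

**What the phantom does not emulate:** acquisition physics, bias fields,
registration error, irregular or heterogeneous lesions,
between-modality noise correlation, and partial-volume effects. Passing
tests therefore demonstrate that the pipeline recovers planted effects
of the stated geometry and SNR — not clinical performance.

## DTI p/q decomposition

MD = Σλᵢ/3, p = √3·MD (the Frobenius norm of the isotropic tensor
component — the convention of the p/q decomposition literature),
q = √Σ(λᵢ−MD)², FA = √(3/2)·q/√Σλᵢ². The identity p² + q² = Σλᵢ² is
enforced as a test invariant. Negative eigenvalues are rejected rather
than clamped; the all-zero triple is an error (FA is 0/0 there), while
the volume-level wrapper maps all-zero background voxels to 0 in all
four outputs as an explicit policy.

## ROI geometry

Distance bands are half-open intervals (d_{k−1}, d_k] of the Euclidean
distance to the CE mask, computed in physical mm with anisotropic
spacing support; "5/10/15/20 mm" are therefore disjoint bands, not
cumulative regions (the band-by-band group plots require disjoint
groups). Masks are strictly binary, voxel indexing is 0-based, and the
bands partition {0 < d ≤ 20 mm} ∩ brain minus the CE lesion and
progression ROI — checked exhaustively against a KD-tree distance
oracle. NAWM is the grid mirror (midsagittal flip) of the abnormal
region plus its 20 mm envelope clipped to the brain, minus any
ipsilateral abnormal voxel; mirroring rather than symmetry registration
is deliberate — registration is out of scope and the phantom brain is
symmetric. An asymmetric brain triggers a warning and the NAWM is
restricted to the intersection.

## Voxel-wise radiomics (294 features)

Support: a 5×5×5 voxel neighborhood centered on the voxel (clipped at
the volume border, no padding). The neighborhood size is a design
default, configurable. Quantization: per-patch min–max binning into 32
levels (constant patches map to level 1); min–max binning makes all
texture features invariant to adding a constant to the patch.

Per modality, 42 statistics: 13 first-order (mean, sd, median, min,
max, variance, skewness, kurtosis, energy, entropy, uniformity, RMS,
mean gray level — entropy/uniformity/mean gray level on the quantized
histogram, the rest on raw intensities), 21 GLCM and 8 GLRLM. GLCM and
GLRLM both use the 13 unique 3D directions at Chebyshev distance 1;
co-occurrence counts are symmetrized and summed over directions before
normalization, run counts are summed over directions.

The printed feature accounting (294 = 91 + 203) implies 29 second-order
statistics per modality, three more than the 26 named ones; the registry
closes the gap with GLCM maximum probability, GLCM sum average and GLRLM
run-length non-uniformity normalized, each flagged `reconciliation=True`
so they can be audited or dropped.

Fixed numerical conventions: population variance (divide by n);
skewness m₃/σ³ and Pearson kurtosis m₄/σ⁴, both 0 for zero-variance
patches; all logarithms base 2 with 0·log 0 ≡ 0 (the information
measures of correlation convert to nats internally so IMC2 keeps its
standard closed form); GLCM correlation features are 0 when a marginal
is degenerate; sum variance is taken about the sum average and
difference variance about the difference average; run percentage is
(number of runs)/(total run length), which equals the per-direction
definition for single-direction matrices and handles direction-summed
matrices uniformly. These rules guarantee every feature is finite on
every patch, which the classifier requires. The numba kernels are
verified patch-by-patch against an independent pure-Python enumeration
oracle on a full seeded volume at 1e-9 relative tolerance.

## Classifier

Architecture: 294 → 10 tanh units → 1 sigmoid: a single hidden layer of
10 neurons by default; depth is configurable. Features are z-scored with training-partition
statistics (stored on the model) because raw feature scales span orders
of magnitude. Training minimizes mean binary cross-entropy with
Møller's scaled conjugate gradient: conjugate directions, a scalar
damping term λ adapted by the comparison ratio Δ (λ ← λ/4 when
Δ ≥ 0.75, increased when Δ < 0.25), finite-difference curvature with
σ₀ = 5·10⁻⁵, λ₀ = 5·10⁻⁷, restart every N iterations, no line search.
Stopping: gradient norm < 1e-8, 250 iterations, or 10 validation checks
without improvement (the weights at the best validation loss are kept).
Training is bit-reproducible given the data, split and init seeds.

The 70/15/15 split assigns round(n·fraction) rows to validation and
test and the remainder to training. Confusion metrics are reported in
percent; ratios with empty denominators are NaN and flagged rather than
silently zeroed. Class imbalance is left as-is (no reweighting): the
peritumoral sampling keeps progression the minority class and the
report shows the resulting PPV/NPV asymmetry. External validation
re-trains the network once per repeat (3 by default) with fresh split
and initialization seeds and pools held-out subjects' voxels; subject
leakage between cohorts is an error.

## Group statistics

Per-subject ROI means feed classical paired t-tests (two-sided p,
Student's t with n−1 df). Zero-variance differences are flagged: t = 0,
p = 1 if the differences vanish identically, ±∞ with p = 0 otherwise.
The 294-feature screen compares each feature's progression-ROI mean
against the pooled non-progression mean across the four bands (pooling
is the default comparator; band-wise tests remain available) and
reports raw p-values — no multiplicity correction by default, since the
screen is exploratory; Benjamini–Hochberg is available as an option.
Normality of the per-subject differences is assumed.

## Problem sizes of the packaged experiments

The parameter-recovery experiment uses 10 training + 4 held-out
subjects on the default 48³ grid with ~3,600 sampled peritumoral voxels
per subject (~5·10⁴ total). Sampling caps the progression share at 30%
so the majority-class rate (70%) leaves headroom between "recovered the
planted effects" (held-out accuracy well above 85%) and "learned
nothing" (accuracy at the majority rate, the zero-effect control). The
type-I calibration runs 10 independent zero-effect cohorts of 8
subjects on a 32³ grid with 300 sampled voxels per subject; its
acceptance band (mean flagged fraction 5% ± 3 points) reflects that the
294 per-seed tests are correlated across features, so the seed-level
flagged fraction is substantially more dispersed than an independent
binomial would suggest.

## Known limitations

- The phantom's effect magnitudes are free parameters, not calibrated
  to patient data; headline cohort numbers from any real study are out
  of reach by design.
- The NAWM mirror assumes an approximately symmetric brain mask.
- GLCM/GLRLM conventions vary across the literature (quantization,
  direction weighting, log base, sum-variance centering); the choices
  above are fixed and documented, and the oracle tests pin them down,
  but feature values are not numerically interchangeable with other
  radiomics toolkits.
- Voxels are treated as i.i.d. by the classifier; spatial correlation
  is present in the phantom noise but not modeled in training or in the
  voxel-pooled validation metrics.
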