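# Methods

## Scope

`roimcr` implements a four-stage analysis of centroided LC-MS metabolomics
data: (1) per-run compression of ragged centroided scans into a dense
regions-of-interest (ROI) feature matrix, (2) column-wise augmentation of
several runs onto a unified m/z basis, (3) bilinear resolution of the
augmented matrix into pure elution/spectra components by alternating
non-negative least squares, and (4) per-component group statistics. A
ground-truth simulator ships as first-class code so every stage is testable
without instrument data.

## ROI search

An ROI is a set of raw `(scan, m/z, intensity)` points that (a) exceed the
signal threshold `thresh`, (b) stay within the mass tolerance `mzerror` of
the ROI's running center m/z, and (c) occur in at least `minroi` scans. The
search is scan-sequential: suprathreshold points of a scan are first grouped
in ascending m/z order into clusters (a point joins the open cluster while
it is within `mzerror` of the cluster's running mean), then each cluster is
matched to the nearest existing ROI center within `mzerror` — ties to the
lower m/z — or opens a new ROI. Centers are recomputed over all members
after every admission (mean by default, median optional), so they track
slow calibration drift. After the last scan, ROIs whose centers drifted
within `mzerror` of each other are pooled (closest pair first), the
occurrence filter is applied, survivors are sorted by center, and the dense
matrix is assembled — co-occurring members of one ROI in one scan are
summed. No peak shape is imposed at any point, and every member point's
measured m/z is kept in the provenance records, so compression is lossless
in the spectral direction.

Empty matrix cells are replaced by independent draws from the uniform
distribution on `(0, 2·f·thresh)` (mean `f·thresh`, default `f = 0.01`),
seeded for reproducibility. A bounded positive noise floor keeps the
downstream non-negative factorization away from exact zeros without
injecting outliers; the distribution only needs the stated mean, and the
bounded uniform is the least committal choice.

Parameter guidance (units): `thresh` is in absolute intensity units —
0.1–1% of the run's maximum intensity is a practical starting band
(`threshold_from_max` helper); `mzerror` (Da/e) should sit between the
instrument's mass jitter and the spacing of ions to be resolved; `minroi`
(scans) corresponds to the expected chromatographic peak width divided by
the scan interval. Occurrences are counted as distinct scans by default; a
consecutive-run mode is available for data where persistence should mean an
unbroken elution stretch.

## Multi-run augmentation

Unification is pairwise and folded over the run list (sequentially, or
within groups first). Centers of the two inputs coincident within
±`mzerror` are merged to the unweighted mean of the two matched values,
one-to-one, nearest pairs first; a leftover center still within tolerance
of an already-merged one has its intensities summed into that column.
Columns present on one side only are kept when their maximum intensity
exceeds `thresh` (max rather than mean, so narrow but real peaks survive),
with the absent block filled by the seeded noise-floor rule; otherwise they
are dropped. Columns are re-sorted by unified center, and each run's rows
remain a contiguous block. The fold order can move a unified center by a
fraction of `mzerror` when inputs carry jitter (pairwise averaging weights
runs unequally); with ions separated well beyond the tolerance the orders
agree exactly, and the tests measure — rather than hide — the divergence on
deliberately borderline data.

## MCR-ALS

The bilinear model `D = C Sᵀ + E` is fitted by alternating exact
non-negative least squares: each row of `D` is an independent NNLS problem
in the fixed spectra (C-step), each column one in the fixed elution
profiles (S-step), solved by the active-set method. Exact subproblem solves
make the Frobenius residual non-increasing at every half-step, which the
test suite asserts on every fitted model. After each S-step the spectra
rows are rescaled to unit Euclidean norm with the scale absorbed into `C`
(reconstruction-neutral, resolves the bilinear scale indeterminacy).

Initial spectra are the "purest" observed rows of `D`: the largest-norm row
first, then iteratively the row with the largest angle to the span of those
already selected (Gram–Schmidt residual fraction). The procedure is fully
deterministic; the `seed` argument is provenance only.

Convergence: relative change of the lack of fit below `tol` (default 0.1%)
or `max_iter` (default 50) iterations — common chemometric defaults.
Diagnostics: `lof = 100·√(ΣE²/ΣD²)` against the raw data matrix, and
`evar = 100·(1 − ΣE²/ΣD²)`. Only non-negativity and spectra normalization
are enforced; for sparse MS data these suffice, and unimodality/selectivity
constraints are deliberately out of scope. Components whose elution column
collapses to ~0 are flagged (`collapsed_components`), never silently
pruned. `select_components` fits a grid of component counts and suggests
the smallest count whose explained-variance gain over the previous one
falls below a threshold (default 0.1 percentage points), flagging the
suggestion low-confidence when no plateau exists; the full table is always
returned because the choice is ultimately the analyst's.

Permutation and scale of components are not identified by the model; tests
and examples therefore match fitted to true components by spectral cosine
(Hungarian assignment) before scoring recovery.

## Biomarker screening

Per component and sample block: area = plain numerical summation of the
elution block (no peak model), height = block maximum. Blocks are flagged
as peak-shaped when the contiguous window around the global maximum (cells
above 5% of the max) holds ≥ 60% of the block area while spanning ≤ 50% of
the block — flat background fails the width test, split double peaks fail
the area test; thresholds are configurable, and the flag annotates rather
than drops components. Group differences use the pooled-variance Student
t-test by default (Welch optional), two-sided, with optional
Benjamini–Hochberg adjustment across components; components with zero
variance and equal means in both groups get p = 1 by convention. Fold
changes are exposed-mean over control-mean, reported on both areas and
heights (NaN when the control mean is not positive).

## Synthetic data

The generator emulates a centroided acquisition: per scan a variable-length
point list. Defaults describe a short UHPLC-like segment — 120 scans at 1 s
spacing; five components with Gaussian elution (σ 4–8 s), apex amplitudes
1.2·10⁴–8·10⁴ a.u. and sparse one- or two-ion spectra in the 370–900 Da/e
range, two of them carrying isotope-like satellites; m/z jitter sd 0.01
Da/e (half the customary 0.05 Da/e tolerance or less); a sparse random
noise floor (Poisson 5 points/scan, exponential intensities of scale 100);
per-run lognormal amount variability of 5% emulating biological replicates.
Studies default to 3 control + 3 exposed runs with per-component amplitude
multipliers on the exposed group. Optional persistent background ions
(log-uniform mean intensities, 20% scan-to-scan CV, a fraction carrying a
companion channel 0.1–0.45 Da/e away, all shared across replicates through
the spec seed) model solvent/contaminant channels; they are what gives the
ROI count its characteristic response to the threshold and tolerance knobs,
and are off by default for clean component studies.

What the generator does not model: chromatographic tailing and fronting,
detector saturation, correlated (chemical) noise, retention-time drift
between runs, profile-mode peak shapes. Passing tests therefore demonstrate
algorithmic correctness under idealized peak shapes and independent noise,
not robustness to every instrument artifact; the pipeline itself assumes
none of the generator's shapes.

Gaussian elution combined with an intensity threshold has one measurable
consequence worth knowing: tails are truncated at the threshold, and a
stronger peak keeps a slightly larger above-threshold fraction of its mass
than a weaker one. An injected 4-fold change is therefore recovered
end-to-end as ≈ 4.004 even with all noise sources disabled (≈ 0.1% at a
threshold of 500 a.u. against an 8·10⁴ apex) — a property of thresholded
integration, not an implementation error; the tests assert recovery at 0.2%
in the noiseless case and 10% under the default noise.

## Numerical choices and degenerate inputs

- All text-bundle floats are written with 17 significant digits
  (round-trip-exact for float64).
- Runs with zero scans, component counts outside `1..min(I, J)`, negative
  data, all-zero matrices (for initialization or diagnostics), and groups
  with fewer than two samples raise validation errors; rank-deficient ALS
  subproblems surface as a numerical error advising fewer components.
- In-scan cluster ties and equidistant ROI matches resolve to the lower
  m/z; post-run center merging proceeds closest pair first.
- The fill-in RNG is `numpy` PCG64 seeded from the user seed; drawing a
  literal 0.0 (probability ~0) is remapped to the interval midpoint so the
  support stays open.
- Profile-mode input is detected only heuristically (median points/scan
  above 2000) and triggers a warning, never a rejection, since centroided
  runs of very complex samples can be dense too.

## Problem sizes

The validation surface is sized for interactive use: micro-runs of ≤ 5
scans × ≤ 8 points for oracle comparison (200 replicates), 120-scan runs
with ≤ 300 background ions for parameter-response checks, 80 × 6 matrices
for factorization recovery, 1500 null components for the type-I rate, and
3v3 studies (720 × ~7 augmented matrices) end-to-end. The algorithms are
dimension-generic; larger runs simply cost proportionally more NNLS solves.

## Known limitations

- The ALS subproblem loops over rows/columns in Python with per-vector
  active-set NNLS; fine at feature-matrix scale (hundreds of columns),
  not tuned for raw-scan scale.
- Rotational ambiguity of bilinear models is not quantified (no band
  boundaries); sparse MS spectra keep it small in practice but it exists.
- Only two-group designs are supported in the screening stage; multi-group
  designs need external ANOVA on the exported area table.
- mzML support covers centroided MS1 spectra with 32/64-bit float arrays,
  plain or zlib-compressed — vendor idiosyncrasies beyond that (numpress,
  MSn, ion mobility frames) are out of scope.
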