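# Methods

## The measures

For a voxel time series \(x_t\), \(t = 0..N-1\), sampled every TR seconds,
the pipeline linearly detrends \(x\), takes the one-sided amplitude spectrum
on the exact DFT bins \(f_k = k/(N\,\mathrm{TR})\),

\[ a_k = c_k\,|X_k|/N, \qquad c_0 = c_{\mathrm{Nyq}} = 1,\ \text{else } c_k = 2, \]

(so a pure cosine of amplitude \(A\) on bin \(k\) yields \(a_k = A\)), and
defines:

* **A** (raw band amplitude): the mean of \(a_k\) over bins with
  \(0.01 \le f_k \le 0.08\) Hz, bounds inclusive.  At the default
  \(N = 162\), TR = 2 s this is bins 4–25 (22 bins).
* **ALFF** (normalised): \(\mathrm{Alff}_i = A_i \big/ \frac1n \sum_j A_j\)
  over the \(n\) in-brain voxels, so every subject map has in-brain mean
  exactly 1 and global intensity scaling cancels.
* **fALFF**: \(\sum_{\mathrm{band}} a_k \big/ \sum_{k \ge 1} a_k\) — the
  band's share of total non-DC amplitude, which lies in \([0, 1]\].

Declared conventions where the lineage of the measure is ambiguous: A is the
*mean* of band amplitudes while fALFF is a *ratio of sums* (the two differ
only by the bin-count factor in the numerator, a per-subject monotone
transform that cannot affect group contrasts); the fALFF denominator uses
amplitudes, not squared power, keeping the statistic in the unit interval
(a `denominator="power"` switch provides the alternative); the DC bin is
excluded (it is ≈ 0 after detrending anyway); no taper, window, or zero
padding; only a *linear* trend is removed in the spectral path — the
quadratic term exists solely in the nuisance-regression design.  Maps are
smoothed (separable Gaussian, \(\sigma = \mathrm{FWHM}/(2\sqrt{2\ln 2})\)
per axis in voxel units, zero-padded boundary, 8 mm FWHM default) *after*
map computation, never on time series.

The discrete Parseval identity — series variance equals summed spectral
power — is used throughout the tests as the exactness contract tying the
time and frequency domains together.

## Quality control

* SFNR = (mean signal over the ROI and frames) / (mean temporal SD over ROI
  voxels), on a cubic ROI (default 3×3×3) at the brain-mask centroid.
* Maximal displacement = max over frames and translation axes of
  |translation − translation at frame 1| (mm).  Rotations do not enter this
  criterion: the exclusion rule is stated against translation-style
  displacement and no rotation conversion is part of it (the framewise
  displacement summary does convert rotations, with a configurable 50 mm
  arc radius, but is reported only).
* Exclusion iff SFNR < 150 **or** max displacement > 4 mm — both strict
  inequalities, both configurable.  A subject at exactly 150 / 4.0 is
  retained.

## Nuisance regression

Per in-brain voxel, OLS residual against an 11-column design: intercept,
linear and quadratic trends (Legendre polynomials on \([-1,1]\) — same
span, better conditioning), six rigid-body motion parameters, and the mean
WM and CSF series.  Compartment masks come from mean tissue-probability
maps thresholded strictly above 0.99 and nearest-neighbour resampled to the
functional grid by the voxel-centre rule
\(\mathrm{src} = \mathrm{round}((i+0.5)\,n_s/n_t - 0.5)\).  Compartment
means are taken from the raw data; the trends are separate columns (the
projection is identical either way up to the shared column space).  The
solve uses unit-normalised columns with pseudoinverse semantics so
collinear designs (motion random walks vs. trends) stay well defined;
columns that are numerically zero — e.g. the recomputed compartment mean of
an already-residualised run, whose direction is floating-point noise — are
dropped, which is what makes the operation idempotent in practice.
Regression happens before smoothing and before ALFF/fALFF computation.

## Group statistics

* Paired t across subjects (original vs. regressed maps), df = n−1;
  zero-variance voxels get t = 0, p = 1 so map algebra stays total.
* Voxel-wise OLS GLM: site (dummy-coded, last site the implicit baseline),
  diagnosis (HC = 0, SZ = 1), age (mean-centred, so the diagnosis effect is
  evaluated at the mean age and the interaction decorrelates from the main
  effect), and age × diagnosis.  Diagnosis is reported as the two one-sided
  contrasts HC>SZ and SZ>HC; the site main effect is a partial F by extra
  sum of squares, invariant to the baseline choice.  Numerically perfect
  fits are reported at a capped statistic (1e6) with p = 0, or t = 0 / p = 1
  when the coefficient itself is null.  With a single site the site factor
  is dropped with a logged notice.
* Significance: Benjamini–Hochberg FDR at q = 0.05 over in-brain voxels
  (independence-flavoured variant, the common neuroimaging choice), then a
  cluster-extent filter keeping components of ≥ 10 voxels under
  18-connectivity (6/18/26 configurable; ≥ rather than > is the declared
  reading of a "10-voxel extent threshold").

## Effect sizes, mega vs. meta

Diagnosis t-maps convert to Cohen's d by the two-sample formula
\(d = t\sqrt{1/n_1 + 1/n_2}\) (declared: no df-based small-sample variant,
and the conversion applies to the covariate-adjusted t).  The mega-analysis
is the pooled GLM with site; the meta-analysis fits each site separately
*without* the site factor (diagnosis + age + age × diagnosis), converts and
combines per-site d maps as a weighted mean with weights equal to total
per-site n — not inverse-variance, matching the sample-size-correction
description of the procedure being emulated.  Reports give ROI-mean d for
both analyses, their ratio, and the per-site range.  ROIs are the injected
effect regions: atlas-based masks are out of scope on a synthetic grid.

## The synthetic cohort generator

The phantom is an ellipsoidal "brain" (default 16×16×12 voxels of 3 mm,
162 frames, TR 2 s — the acquisition geometry of the motivating protocol at
desk scale) with a central CSF box, a WM shell, and a GM remainder.  Voxel
series are

    offset_site + gain_site · g(v) · [ α(v,group)·s_low(t) + β(v)·s_phys(t)
                                       + γ(v)·m1(t) + ε(t) ]

* `s_low`: unit-variance 0.01–0.08 Hz noise built on exact DFT bins (flat
  magnitude, uniform random phases).  Band membership is exact, per-bin
  amplitude deterministic — that is what makes clean oracles possible.
* `α`: low-band SD (default 3, ~0.3% of the 1000-unit baseline), multiplied
  by the region's amplitude ratio r = SZ/HC for SZ subjects inside an
  effect region; WM/CSF get 0.3×.
* `s_phys`: respiration (0.3 Hz, amplitude 1) and cardiac pulsation
  (1 + 10/324 ≈ 1.031 Hz, amplitude 6) as continuous-time sinusoids sampled
  every TR, so aliasing emerges from sampling: respiration lands at
  0.20 Hz (out of band), cardiac at exactly bin 10 = 0.0309 Hz (in band).
  β is 1 in WM/CSF and 0.5 in GM.  The cardiac term was deliberately given
  the larger amplitude: aliased in-band physiology is the mechanism by
  which nuisance regression lowers fALFF, and the out-of-band respiratory
  removal plus the degrees-of-freedom loss of the regression act in the
  opposite direction, so the in-band channel must dominate for the cohort
  to behave like resting-state data in this respect.
* `γ·m1`: the x-translation random walk (step SD 0.02 mm) coupled through a
  left–right linear gradient (gain 2 signal units per mm at the brain edge).
* One "vendor outlier" site gets gain 1.15, offset +300, and a
  multiplicative Gaussian bump (amplitude 0.3) in the anterior/inferior
  brain, emulating regional B0-related differences between scanner makes;
  since normalised ALFF cancels global gain, the bump is exactly what makes
  the site F-test show a regional pattern.
* The stock 306-subject cohort mirrors the per-site group sizes and mean
  ages of the motivating seven-site study, with 12% heavy movers (25× step
  SD) and 6% high-noise runs (3× white SD) so the QC stage has something
  real to do (it retains ~80%).

Determinism: per-subject seeds are `SeedSequence((master_seed, index))`
(roster covariates) and `SeedSequence((master_seed, 1_000_000 + index))`
(data), with the index running over sites in order, HC before SZ — the same
master seed reproduces the cohort byte for byte.

### Effect-size calibration

The implied voxel-level Cohen's d for an amplitude ratio r is estimated by
Monte-Carlo on the single-voxel noise model (2 000 virtual subjects per
group by default), neglecting the subject-mean normalisation (a shared
scale with negligible between-subject variance) and the motion-coupling
term (near zero over the centrally-placed effect regions).  Because the
amplitude mean is linear in r and the SD is noise-dominated, d(r) is linear
in r − 1; `calibrate_ratio` estimates the slope at r = 1.1 and inverts.
Under white noise alone the closed form is \(d \approx (r-1)\sqrt{N}\,
\alpha/\sigma_w\), i.e. r ≈ 1.07 for d = 0.8 at the defaults; the
Monte-Carlo version additionally absorbs the physiological terms.

### What the generator does and does not emulate

It reproduces the features the pipeline is sensitive to: band-limited
group-dependent amplitude, aliased physiology loading on compartments,
motion-coupled signal, site gain/offset/regional distortion, random-walk
motion, QC-failing tails.  It does **not** model hemodynamic response
shapes, spatial autocorrelation of the neural signal (voxels are spectrally
independent given the shared physiological and motion terms), anatomy,
scanner drift beyond polynomial trends, or non-Gaussian artefacts.  Passing
tests therefore certify the *estimators and inference machinery* — spectral
exactness, calibration, recovery, the direction and ordering of effects —
not performance on real scans.

## Study problem sizes

The analysis scripts and acceptance checks run at sizes chosen to keep the
full suite comfortably interactive while leaving Monte-Carlo error well
inside the tolerances tested: type-I calibration on 20 replicate two-site
cohorts (15/group/site); effect recovery on 4 sites × 20/group at
calibrated |d| ≈ 0.8; mega/meta consistency on 10 replicate homogeneous
4-site cohorts; regression direction on 10 replicate 12-subject cohorts;
the stock cohort at the full 306 subjects.

## Known limitations

* The calibration target d refers to the unsmoothed, unnormalised voxel
  statistic; recovery and mega/meta studies therefore run the group model
  on unsmoothed maps, attributing spatial sensitivity and specificity to
  the statistics rather than to the 8 mm kernel (smoothing is implemented
  and tested separately, and bleeds effects across region borders exactly
  as expected when enabled).
* fALFF of a noiseless single-bin cosine equals 1 only when the cosine is
  orthogonal to the trend line (e.g. phase-centred); otherwise detrending
  introduces genuine broadband leakage.  This is a property of the measure,
  not an implementation artefact.
* The BH-FDR variant assumes independence/PRD; under the generator's weak
  cross-voxel dependence (shared physiology/motion) this is the standard,
  slightly anticonservative-in-theory, robust-in-practice choice.
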