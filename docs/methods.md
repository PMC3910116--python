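# Methods

This note documents the models behind each stage, the conventions and
numerical choices, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Thermal denaturation

A CD melt at 222 nm is modeled as a reversible two-state equilibrium with
linear pre- and post-transition baselines. Within one curve,

    dG(T) = dHm * (1 - T/Tm),
    K(T)  = exp(-dG/(R T)),
    theta(T) = [theta_N(T) + theta_U(T) K(T)] / (1 + K(T)),

with R = 1.987204e-3 kcal/(K mol) and theta_N, theta_U linear in T. The
heat-capacity term is deliberately omitted per curve: over the narrow
transition region it is poorly identifiable from a single melt, and the
workflow recovers dCp instead as the OLS slope of dHm on Tm across a pH
series (melting temperature shifts with pH; the enthalpy at the shifted Tm
tracks dCp). Free energies at other temperatures use the modified
Gibbs–Helmholtz relation

    dG(T) = dHm (1 - T/Tm) - dCp [(Tm - T) + T ln(T/Tm)],

evaluated by default at T = 298.15 K. All internal math is in Kelvin
(I/O accepts Celsius); ln(T/Tm) is only meaningful on an absolute scale.

Fitting is plain nonlinear least squares (scipy `curve_fit`) over six
parameters {Tm, dHm, 4 baseline coefficients}. Initialization: Tm at the
extremum of a Savitzky–Golay-smoothed derivative (window widened if the
apparent extremum sits on a scan edge, i.e. is noise-dominated), dHm at
50 kcal/mol, baselines from the outer 15% of points. Fits are rejected —
never silently returned — when the transition is not interior to the scan,
when dHm comes out non-positive, or on non-convergence. Reversibility is
the ratio of post/pre renaturation CD at 222 nm with the conventional 95%
pass threshold.

A curve is required to have at least 20 points; the fit reports standard
errors from the covariance of the least-squares solution. Reported
precision mirrors the conventional table format (Tm 0.1 C, dHm 0.1, dCp
0.01, dG 0.01 kcal/mol); all comparisons and validators use unrounded
values.

## Binding kinetics (BLI)

Association and dissociation phases are fit independently per analyte
concentration:

    association:  y = a (1 - exp(-kobs t)) + y0 t    (y0 = drift slope)
    dissociation: y = y0 + a exp(-koff t)            (y0 = constant offset)

kobs regressed on concentration gives kon (slope) and an intercept koff
used as a consistency check; the headline koff is the inverse-variance
weighted mean of the per-concentration dissociation fits, since those are
the direct estimates and a single per-variant koff is wanted. KD = koff/kon
holds to machine precision by construction. Per-concentration fits are kept
independent (no global fit) to match the two-step kobs-then-regression
procedure. The full phase is fit without trimming; that is configurable by
slicing traces before fitting. Constant traces are rejected (amplitude ~ 0
makes the rate unidentifiable), as are non-positive fitted rates.
Concentrations are molar internally, micromolar at table I/O.

## Chaperone activity by standard-curve back-interpolation

Three calibration families map chaperone:client ratio x to a readout y:

    exponential y = A + B exp(-k x)       alpha-LA scattering endpoints
    quadratic   y = a2 x^2 + a1 x + a0    aldolase aggregation slope
    power       y = c (x + x0)^p          aldolase refolding yield

Pinned wild-type calibrations: the 400 s alpha-LA endpoint curve
(0.004, 0.108, 8.46), the aldolase slope curve (29.0861, -65.0189,
37.9414) and the refolding curve (1.27711, 0.02196, 0.18859). Each family
is inverted analytically; the quadratic inversion always takes the root on
the decreasing branch left of the vertex (-a1/(2 a2)), which is the
physically meaningful branch of a calibration that falls with added
chaperone. Readouts outside the attainable range raise an error naming the
violated bound — out-of-range observations must be re-measured at a lower
added ratio, never extrapolated. Fitted calibrations are rejected if not
strictly monotone over the data span (a non-monotone calibration cannot be
inverted).

Fold activity is effective_ratio/added_ratio, averaged over every
observation x curve combination (for alpha-LA: 3 added ratios x 4 endpoint
curves x duplicates). The reported error combines the scatter of the
individual folds (SEM) with first-order propagation of the calibration's
coefficient covariance through the inversion; for calibrations entered as
fixed printed coefficients that second term is zero.

Aggregation-rate slopes are fit over exactly the 50–600 s window,
inclusive. Endpoint extraction linearly interpolates between bracketing
samples, which reduces to exact lookup on grids containing the requested
time.

## In vivo specific activity

The MIC is the lowest tested penicillin concentration with no growth at the
scoring dilution (10^-3 by default; the scoring rule is configurable since
spot-titration protocols differ). Growth at every concentration returns an
infinite sentinel; a growth column that is not monotone along penicillin is
flagged in the result, never silently repaired. Expression levels are the
intensity-vs-loading slope of the target band divided by the loading
control's slope, rescaled to wild type = 1. MIC_norm divides a variant's
maximal MIC by the wild-type MIC at the matched expression level,
interpolated piecewise-linearly along the wild-type induction titration;
levels outside the titration range raise rather than extrapolate.
Correlations are ordinary least squares on the linear scale with Pearson r
and R^2 = r^2.

## Top-down HDX

Deuterons per fragment are (deuterated - unlabeled centroid)/1.006277 Da.
Exchangeable sites are backbone amide NH protons: prolines and the
N-terminal residue are excluded. Fractional deuteration divides by the
number of sites times the D2O fraction (0.8 by default, the 1:4 mixing
ratio). The bookkeeping convention, chosen so c- and z-attributions agree
exactly on full coverage, is that c_n carries the amides of residues 2..n
and z_n those of its covered residues; the increment between consecutive
fragments therefore attributes exchange to a single residue (residue n for
c_n vs c_(n-1); residue L-n+1 for z_n vs z_(n-1)). Protection is positive
when the client-bound complex takes up fewer deuterons — a sharp drop in
the c-series differential plot. The "percent protected protons" flexibility
metric scores an amide as protected when its fractional deuteration is at
or below 0.2; the threshold is a package default (recorded in output
metadata) since no standard value exists, and conclusions should be checked
for threshold sensitivity. Back-exchange and hydrogen scrambling are not
modeled: the quench-flow/ECD format justifies ignoring scrambling, and all
statements are state-to-state comparisons where back-exchange largely
cancels. Kinetic (multi-timepoint) HDX modeling is out of scope.

## Crosslink candidate selection

Digestion: trypsin cleaves after K or R with no proline exception
(observed digests include cleavage before proline), with configurable
missed cleavages; proteinase K is modeled as unspecific — all substrings
within configurable length bounds (default 3–20). Candidate enumeration
applies each chemistry's reactivity rule: CBDPS links amine to amine (K
side chains and the protein alpha-amine), ABAS links an amine on one side
to any residue on the other (photo end), EDC condenses carboxyl (D/E or
the protein C-terminus) with amine losing one water (18.010565 Da), and
PICUP couples tyrosine to tyrosine losing two hydrogens (2 x 1.007825 Da).
The added masses of the isotope-coded reagents are config inputs with no
asserted defaults, since reagent compositions vary; zero-length chemistries
need none. Monoisotopic masses and nitrogen counts come from pyteomics'
elemental compositions.

Isotope-pair selection finds feature pairs split by 8.05 Da (CBDPS-H8/D8),
6.02 Da (ABAS-12C6/13C6), or — for zero-length chemistries with an
equimolar 14N/15N-labeled client — by the client peptide's nitrogen count
times 0.9970349 Da, within a 0.01 Da default tolerance. Candidate-feature
matching keeps candidates within a ppm tolerance (10 ppm default,
Orbitrap-class) sorted by |ppm error|. MS/MS-level scoring and FDR
estimation against decoys are out of scope.

## Synthetic data: what it does and does not emulate

Each generator draws from an independent child stream of one root seed
(numpy `default_rng([seed, stream_id])`), so identical configs give
bit-identical output and assays are mutually independent. Noise is
additive Gaussian on the measured signal — the simplest model consistent
with replicate-level standard errors; per-point noise magnitudes are
package defaults exposed in config, since real instruments vary. Default
grids: melts 283.15–353.15 K at 0.25 K, BLI association 0–600 s and
dissociation 0–900 s at 1 s.

Specific constructions: BLI amplitudes follow Langmuir occupancy
amplitude_max * c/(c + KD); the alpha-LA trace ramps to the 400 s-curve
endpoint and plateaus before 300 s so that all four endpoint reads return
the calibrated value (only the 400 s calibration is pinned; the synthetic
endpoint curves at 300/500/600 s reuse its coefficients); the aldolase
trace is linear with the calibrated slope; spot grids grow wherever
penicillin is below the true MIC; western series are linear in loading.
The generators do not emulate instrument artifacts (spectral interference,
photobleaching, plate-edge effects), aggregation kinetics (nucleation/
elongation), partial reversibility, mass-transport-limited binding or
isotope-envelope structure. Passing parameter-recovery tests therefore
demonstrates correctness of the estimators under the stated models, not
robustness to every real-data pathology.

## Pipeline and problem sizes

The pipeline's built-in study runs eight variants. Per variant it fits a
7-point pH series of full melts (281 points each), a 5-concentration BLI
traceset (601/901-point phases), the three activity assays (3 ratios x 4
endpoints x duplicates for alpha-LA; 3 replicates each for the aldolase
assays, with automatic re-measurement at added ratio 0.1 when a highly
active variant leaves the calibrated range), and the spot-grid/western
normalization. The pH series synthesizes melts with Tm offsets of -10..+5 K
around the reference and enthalpies on the dCp line; buffer chemistry
itself is not modeled — the series exists to exercise the dHm-vs-Tm
regression. A zero-noise run reproduces every configured truth exactly and
completes in well under a second; simulation studies in the test suite use
100 seeds per condition. The summary validator recomputes KD and dG from
primary columns and distinguishes rounding-level deviations (flagged) from
genuine inconsistencies.

## Known limitations

* Three-state or irreversible unfolding, chemical denaturant melts and DSC
  are out of scope; dCp = 0 within one melt is an assumption, not a fact
  about any particular protein.
* The kobs-line intercept and the dissociation koff can disagree on real
  data with drift or rebinding; only the disagreement beyond combined
  errors is diagnostic.
* Only one alpha-LA endpoint calibration is pinned; treating the other
  endpoints with the same coefficients is a synthetic-data convention.
* HDX residue attribution needs consecutive fragment coverage; gaps leave
  residues unattributed rather than interpolated.
* Crosslink theoretical masses for isotope-coded reagents depend on the
  configured linker mass; absolute mass tables cannot be reproduced without
  the reagent composition.
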