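# Methods

This note records the models implemented in `trsx`, the choices made
where the underlying procedures are conventionally under-specified, and
what the synthetic-data generators do and do not emulate.

## Sequential kinetic decomposition of difference spectra

A flash-photolysis series of difference absorption spectra is stored as
a matrix `D(λ, t)` (wavelengths × delays, ΔOD). The late photocycle of a
microbial rhodopsin is modelled with two spectral intermediates, a
blue-shifted M state (deprotonated Schiff base) and a red-shifted O
state, in a sequential chain M →(k1)→ O →(k2)→ ground:

    c_M(t) = exp(−k1 t)
    c_O(t) = k1/(k2−k1) · (exp(−k1 t) − exp(−k2 t)),

with the analytic limit `c_O = k1 t exp(−k1 t)` taken when
|k1−k2| < 1e−9·k1. Time is in milliseconds throughout.

The fit is a variable projection: the basis spectra are restricted to
the span of the two leading left singular vectors of `D`, so for each
trial rate pair the optimal amplitudes solve a 2×2 linear system and the
residual is exact. Trial pairs come from a 40×40 log-spaced grid over
1e−4–1 /ms, and the best pair is polished by Nelder–Mead in log-rate
space. Data whose second singular value is below 1e−6 of the first are
rejected as non-identifiably rank 1.

**Rate-exchange degeneracy.** `(k1, k2)` and `(k2, k1)` span the same
two-exponential space, so both orderings fit any rank-2 series equally
well; the swapped solution absorbs the difference into its O basis
spectrum (which then contains a large admixture of the M spectrum). The
fitter resolves the ordering by spectral distinctness: it keeps the
assignment whose two basis spectra have the smaller absolute cosine
similarity. This selects the physical assignment whenever the two
intermediate spectra are less mutually similar than their mixtures,
which holds for well-separated band positions; when the rates are nearly
equal the two orderings are kinetically indistinguishable and the choice
is immaterial.

**Normalisation.** The model traces satisfy `c_M(0)+c_O(0) = 1`, i.e.
occupancies are expressed as fractions of the initially photoexcited
population; the overall ΔOD amplitude (the product of photoexcited
fraction and extinction contrast) is absorbed into the basis spectra.
The `scale` field records the trace renormalisation factor, which is
1.0 in this parametrisation; separating a physical photoexcited
fraction requires externally calibrated basis spectra.

Derived observables: the crossover time (first `t > 0` with
`c_M = c_O`) and the half-decay time (`c_M + c_O = 1/2`) are found by a
dense bracketing scan followed by Brent bisection to 1e−6 ms; both may
be absent (no crossing within 100 slowest time constants; conserved
total when k2 = 0) and are then reported as `None`.
`rates_from_timings` inverts the two conditions to a rate pair by a
Newton-type root search, used to construct generators whose observable
timings are prescribed.

**Repeat averaging.** Repeated measurements are averaged after outlier
rejection: a repeat is dropped when the RMS deviation of its matrix from
the element-wise median matrix exceeds `k` (default 3) times the median
of all repeats' RMS deviations — a median-based analogue of a k-sigma
cut, robust to the outliers it removes. The default `k = 3` is the
conventional moderate cut; the rejection rule is a package choice.

**Beam-overlap correction.** In a flowing-jet experiment the
photoactivated column translates out of the X-ray beam. The correction
factor is modelled as the linear overlap of a column of height `H` with
a beam of vertical size `h` after travel `v·t`:
`clamp((H + h − v t)/(H + h), 0, 1)`. This geometric form is a package
choice; only the existence of the correction, not its functional form,
is conventionally specified.

## Photon budget

Closed forms, SI constants (N_A = 6.02214076e23, h = 6.62607015e−34 J·s,
c = 2.99792458e8 m/s):

* mean fluence across the FWHM circle: `F = ½ P τ / (π (FWHM/2)²)` —
  exactly half a Gaussian beam's power falls inside the FWHM;
* absorption cross-section: `σ = 1000 ln10 ε / N_A` (ε in M⁻¹cm⁻¹);
* photons absorbed per chromophore: `F σ / (hc/λ)`;
* depth-average transmission over a uniform path of optical density
  `OD`: `(1 − 10^−OD)/(OD ln10)`;
* jet velocity `v = Q/(π r²)`, per-flash translation `v/f_rep`, column
  height `v · t_loss`.

With the default instrument parameters (2.6 mW, 5 ms, 75 µm FWHM,
ε = 48 000 M⁻¹cm⁻¹, λ = 488 nm) the plain formula gives ≈66 photons per
chromophore at the jet surface. Published discussions of this setup
quote ≈49 for the same inputs; the plain product does not reproduce that
number (a wavelength-dependent absorbance correction relative to the
498 nm peak may be implicit there). The package reports the formula
value and does not apply an undocumented correction factor; the
depth-averaged quantity is computed from whichever surface value the
caller supplies.

## Isomorphous difference maps

The difference map is the Fourier synthesis
`Δρ(x) = (1/V) Σ_h ΔF(h) e^{iφ_dark(h)} e^{−2πi h·x}` with
`ΔF = F_light − F_dark` on the common index set and phases from the
dark-state model. Friedel mates are completed with conjugate
coefficients so the synthesis is real; `(0,0,0)` is skipped. All
computation is in P1 — symmetry expansion belongs to the upstream
merging tools. Maps are normalised by σ = the RMS of the grid values,
the conventional contouring unit for difference maps.

Numerical choices: the grid satisfies spacing ≤ d_min/3 on every axis
and is enlarged if needed so no Miller index aliases; extrema are
reported on grid points (no interpolation — at d_min/3 spacing the
quantisation is well below the precision at which features are quoted);
site values use minimum-image distances, which is exact for the
rectangular cells used here and conservative for oblique ones.

Amplitude scaling between light and dark sets is least-squares
(`k` minimising `Σ(F_dark − k F_light)²`), either global or per
resolution shell (default 20 equal-count shells, reduced so each shell
keeps ≥10 reflections). The scaling scheme is a package choice; the
upstream merging pipeline's scheme is not portable.

Peak search finds 26-neighbour local extrema above the threshold,
greedily merged within 1.5 Å (strongest kept), assigned to the nearest
model atom. `feature_at_site` reports the signed grid extremum within a
radius (default 1.2 Å) of a site, in σ units.

## 1D sequence projection

Every grid point with |value| ≥ threshold·σ lying within a cutoff of
the model is attributed to the residue of its nearest non-hydrogen atom
(exact ties to the lowest atom serial); |value| accumulates into
per-residue positive/negative amplitudes, and above-threshold density
beyond the cutoff is summed into a reported `dropped_amplitude`, making
the accounting exactly conservative. Defaults: threshold 3.0σ (the
contouring convention) and cutoff 2.0 Å; both are parameters. Summing
|values| (rather than recording per-residue extrema) is the documented
convention here.

Profiles are compared by Pearson correlation of the concatenated
(positive, negative) vectors; zero-variance input yields an undefined
(`None`) result. Region means average `pos+neg` over inclusive residue
ranges; the built-in region table covers the sensory rhodopsin II
helices (A 3–26 … G 189–219) and the four regions tracked in time
(helix C 71–81, D/E 118–124, F + F/G loop 143–171, helix G 197–213).

## Bootstrap error estimation

The resampling unit is the individual amplitude observation within each
Miller index; per-image resampling happens upstream of this package's
inputs. Each of `n_boot` (default 100) replicates resamples light and
dark observations independently with replacement within each index,
merges by unweighted mean, recomputes the difference map, and evaluates
each feature site. The reported error bar is the per-site sample
standard deviation (ddof 1) of the raw density values, expressed in
units of the point-estimate map's σ — a fixed normalisation, so
replicate-to-replicate fluctuation of the map RMS does not leak into
the error bars.

Note the small-sample property of the bootstrap of a mean: its expected
variance is `(N−1)/N² · σ²` for `N` observations per index, so the
error-bar ratio between multiplicities `N` and `4N` approaches 2 from
below (≈1.79 at N=4, ≈1.90 at N=8).

For coordinate ensembles, member i of the light ensemble is paired with
member i of the dark ensemble, the per-residue Cα separation computed
for each pair, and the sample standard deviation over replicates
returned. With two members this reduces to `|s₁−s₂|/√2`.

## Superposition and displacements

Kabsch least-squares rigid superposition with a proper rotation
enforced; Cα atoms matched strictly by (chain, residue number), with
unmatched residues counted rather than fatal (paired depositions model
different ranges). Collinear matched sets are flagged as degenerate.
Displacement profiles are per-residue Cα distances; the global
superposition is optional and off by default when comparing conformers
extracted from one refined entry (they share a crystal frame), on when
comparing separate entries. Conformer splitting keeps blank-altloc atoms
in both submodels and drops the opposite tag.

## Synthetic data

* **Spectra.** Basis difference spectra are built as (intermediate
  Gaussian band − ground-state Gaussian band) on a 350–650 nm axis with
  the ground bleach at 498 nm. The M and O band centres default to 390
  and 530 nm — physically plausible positions for a blue-shifted M and
  red-shifted O, chosen as generator defaults, not measured values.
  Band widths (28/25/30 nm sd), relative amplitudes (1.0/0.9) and the
  overall 0.02 ΔOD scale are likewise plausibility choices. Default
  rates are (1/81, 1/220) ms⁻¹, the chain whose crossover and
  half-decay are ≈63 and ≈240 ms; default delays are 30 points over
  0–500 ms. Noise is i.i.d. Gaussian per matrix element; `n_repeats`
  builds an independently noisy stack. Signal-to-noise is defined as
  RMS(clean)/sd.
  Not emulated: baseline drift, wavelength-dependent noise,
  scattering backgrounds, photoproduct accumulation, and the J/K/L
  early intermediates — so passing tests demonstrate correctness of the
  decomposition under the two-state model, not robustness to every
  instrumental artefact.
* **Toy crystals.** Isotropic Gaussian atoms in a P1 cell with exact
  analytic structure factors
  `F(h) = Σ w_j exp(−2π²σ_j²|s|²) exp(2πi h·x_j)`, evaluated by direct
  summation — the independent oracle for the FFT synthesis. Gaussian
  atoms replace tabulated scattering factors deliberately: the oracle
  stays closed-form and exact. Perturbations (delete/shift/re-weight an
  atom) emulate light-induced changes such as water disordering. Not
  emulated: crystallographic symmetry, anomalous scattering, bulk
  solvent.
* **Observations and models.** Redundant observations replicate each
  amplitude with Gaussian noise (floored at zero, negligible at the
  noise levels used). Synthetic protein models are ideal Cα helices
  (2.3 Å radius, 1.5 Å rise, 100°/residue) with optional per-residue
  shifts and Gaussian jitter for ensemble fixtures.

All randomness flows from explicit integer seeds; fixed seeds are
bit-reproducible.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data: toy crystals of 5–6 atoms at 1.5–2 Å in ~10 Å cells (~200–1000
reflections), spectral series of 101 wavelengths × 30 delays, 20–50
Monte-Carlo seeds, and 100 bootstrap replicates. These sizes were
chosen to make every oracle exactly computable while keeping full runs
in the minutes range.

## Known limitations

* P1 only; symmetry-expanded input is accepted but symmetry is not
  exploited.
* No weighted difference-map coefficients (plain ΔF only) and no
  extrapolated-map or occupancy-refinement schemes — the package
  analyses refined models, it does not produce them.
* The rate-ordering tie-break can mislabel M and O if the true
  intermediate spectra are more similar to each other than to their
  mixtures; the rates and residual are unaffected.
* Coordinate error bars consume externally generated (or synthetic)
  model ensembles; no re-refinement per bootstrap replicate.
* The photostationary decomposition reports unconstrained least-squares
  coefficients; no non-negativity is imposed.
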