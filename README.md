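# trsx

Analysis toolkit for time-resolved serial synchrotron crystallography
(TR-SSX) of photoactive membrane proteins — built around the pump-probe
study of a microbial rhodopsin photocycle in a lipidic cubic phase (LCP)
microjet, but applicable to any two-intermediate flash-photolysis /
difference-map experiment.

It is aimed at structural biologists who already have merged reflection
amplitudes, refined models and time-resolved difference spectra, and who
need the downstream analysis:

* **Kinetics** — decompose a wavelength × delay matrix of difference
  absorbances into M and O intermediate basis spectra and occupancy
  traces under the sequential chain M →k1→ O →k2→ ground, with
  c_M(t) = e^(−k1 t) and c_O(t) = k1/(k2−k1)·(e^(−k1 t) − e^(−k2 t)).
  Basis spectra are optimised as linear sums of the first two SVD
  components (variable projection over a log-spaced rate grid, then
  local refinement). Derived observables: the M/O crossover time and the
  half-decay time of the total photoexcited population.
* **Photon budget** — closed forms for the pump fluence averaged over
  the FWHM spot, the absorption cross-section σ = 1000·ln10·ε/N_A, the
  dimensionless F·σ/hν photons-per-chromophore product, depth-averaged
  attenuation (1 − 10^−OD)/(OD·ln10), and jet kinematics (velocity from
  flow and nozzle diameter, translation per flash, illuminated column
  height).
* **Difference maps** — σ-normalised isomorphous difference Fourier
  maps, Δρ = FT[(F_o(light) − F_o(dark))·exp(iφ_dark)], with amplitude
  scaling, peak search and signed feature values at atomic sites.
* **1D projection** — per-residue positive/negative difference-density
  amplitudes, profile correlations between time points, and mean
  amplitudes over named helix regions.
* **Bootstrap** — error bars for density features and coordinate
  separations from resampled amplitude observations (default 100
  replicates).
* **Structures** — Kabsch Cα superposition/RMSD, conformer splitting of
  partial-occupancy models, and per-residue displacement profiles.
* **Synthetic data** — generators with exact ground truth for every
  input above, including toy crystals of Gaussian atoms whose structure
  factors have a closed form (the oracle for the map machinery).

## Worked example

Instrument budget from the experiment's parameters (defaults match the
published setup — 2.6 mW / 5 ms / 75 µm pump at 488 nm, 0.2 µl/min
through a 75 µm nozzle at 4 Hz):

```sh
$ trsx photon-budget
{
  "fluence_mj_cm2": 147.12990294717434,
  "cross_section_cm2": 1.8352956011561942e-16,
  "photons_per_chromophore_surface": 66.33611935627715,
  "depth_average_factor": 0.7524304338715173,
  ...
  "jet_velocity_um_per_s": 754.5123228060223,
  "translation_per_flash_um": 188.62808070150558,
  "column_height_um": 90.54147873672268
}
```

Reading: each 5 ms flash deposits ≈147 mJ/cm² within the FWHM spot; the
jet flows down at ≈754 µm/s, carrying crystals ≈189 µm between flashes,
and the column photoactivated during the ≈120 ms observation window is
≈91 µm high. A chromophore at the jet surface absorbs ≈66 photons by
the plain F·σ/hν formula, reduced by the factor 0.752 when averaged
through a crystal of OD 0.26 (see `docs/methods.md` for the discussion
of this surface value).

Kinetic decomposition of a synthetic difference-spectrum series whose
true rates are (1/81, 1/220) ms⁻¹:

```sh
$ trsx simulate --what spectra --out-dir demo --noise-sd 1e-4 --seed 4
$ trsx decompose-spectra --input demo/spectra.csv
{
  "k1_per_ms": 0.012298692647885426,
  "k2_per_ms": 0.004564688345039593,
  "tau1_ms": 81.30945529173256,
  "tau2_ms": 219.07300661318777,
  "crossover_ms": 63.081529197361775,
  "half_decay_ms": 240.42492830838245,
  "scale": 1.0,
  "residual_rms": 9.574467063025518e-05,
  "svd_rank_gap": 0.01676152567310607
}
```

Reading: the fitted time constants (81.3, 219 ms) recover the truth to
well under 1%; the M and O occupancies cross at 63.1 ms and their sum
falls to half the initial photoexcited population at 240 ms.

The other subcommands (`diffmap`, `project1d`, `bootstrap-features`,
`displacements`, `filter-cells`) are thin wrappers over the library;
`trsx simulate --what crystal|model` writes matching synthetic inputs so
every stage can be exercised offline. The library API mirrors the CLI —
see the module docstrings under `src/trsx/`.

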