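"""Bootstrap error estimation for difference-density features and coordinates.

Difference-map features carry no analytic error bar: the accepted remedy
is to resample the underlying amplitude observations with replacement,
recompute the difference map for each replicate, and quote the standard
deviation of each feature over (by default) 100 replicates.  The same
logic applies to coordinate displacements between ensembles of models
refined against resampled data.

The resampling unit here is the individual amplitude observation within
each Miller index (per-image resampling happens upstream of merged
data).  Resampled observations are merged by unweighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffmap import (
    PhaseSet,
    ReflectionSet,
    compute_difference_map,
    feature_at_site,
)

__all__ = [
    "ObservationSet",
    "bootstrap_feature_errors",
    "coordinate_separation_errors",
]


@dataclass
class ObservationSet:
    """Redundant amplitude observations: repeated |F| measurements per index."""

    cell: object            # gemmi.UnitCell or 6-tuple
    hkl: np.ndarray         # (N, 3) with repeats
    values: np.ndarray      # (N,)

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.hkl.ndim != 2 or self.hkl.shape[1] != 3:
            raise ValueError("hkl must be (N, 3)")
        if self.values.shape != (self.hkl.shape[0],):
            raise ValueError("values length must match hkl")
        # group rows by index; within-group order fixed by sorting on the
        # value so resampling draws are invariant to input line order
        groups: dict[tuple, list] = {}
        for i, h in enumerate(map(tuple, self.hkl)):
            groups.setdefault(h, []).append(i)
        self._groups = {
            h: np.array(sorted(idx, key=lambda i: self.values[i]))
            for h, idx in sorted(groups.items())
        }

    @property
    def unique_hkl(self) -> np.ndarray:
        return np.array(list(self._groups), dtype=int)

    def multiplicity(self) -> np.ndarray:
        return np.array([len(v) for v in self._groups.values()])

    def merge_mean(self) -> ReflectionSet:
        amps = np.array([self.values[idx].mean() for idx in self._groups.values()])
        return ReflectionSet(self.cell, self.unique_hkl, amps)

    def resample(self, rng: np.random.Generator) -> ReflectionSet:
        """One bootstrap replicate: within-index resampling, merged by mean."""
        amps = np.empty(len(self._groups))
        for j, idx in enumerate(self._groups.values()):
            pick = rng.integers(0, len(idx), size=len(idx))
            amps[j] = self.values[idx[pick]].mean()
        return ReflectionSet(self.cell, self.unique_hkl, amps)


def bootstrap_feature_errors(
    light_obs: ObservationSet,
    dark_obs: ObservationSet,
    phases: PhaseSet,
    feature_sites,
    n_boot: int = 100,
    seed: int = 0,
    radius_A: float = 1.2,
    d_min: float | None = None,
) -> np.ndarray:
    """Per-site standard deviation of difference-density features.

    For each of ``n_boot`` replicates the light and dark observations
    are independently resampled with replacement within each Miller
    index, merged by mean, the difference map recomputed, and the signed
    extremum at every site (within ``radius_A``) recorded.  Returns the
    per-site sample standard deviation across replicates, expressed in
    units of the point-estimate map's sigma (a fixed normalisation, so
    replicate-to-replicate fluctuation of the map rms does not leak into
    the error bars).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    lh = {tuple(h) for h in light_obs.unique_hkl}
    dh = {tuple(h) for h in dark_obs.unique_hkl}
    only = lh ^ dh
    if only:
        raise ValueError(
            f"{len(only)} indices present in only one state, e.g. {next(iter(only))}"
        )
    sites = [np.asarray(s, float) for s in feature_sites]
    ref_map = compute_difference_map(
        light_obs.merge_mean(), dark_obs.merge_mean(), phases, d_min=d_min
    )
    ref_sigma = ref_map.sigma
    if ref_sigma == 0:
        ref_sigma = 1.0  # all-zero difference: report absolute spreads
    rng = np.random.default_rng(seed)
    vals = np.empty((n_boot, len(sites)))
    for b in range(n_boot):
        light = light_obs.resample(rng)
        dark = dark_obs.resample(rng)
        rsmap = compute_difference_map(light, dark, phases, d_min=d_min)
        for j, s in enumerate(sites):
            vals[b, j] = feature_at_site(rsmap, s, radius_A) * rsmap.sigma
    return np.std(vals, axis=0, ddof=1) / ref_sigma


def coordinate_separation_errors(light_ensemble, dark_ensemble) -> dict:
    """Per-residue std of the C-alpha separation across replicate model pairs.

    The ensembles are sequences of equal-topology models (gemmi
    structures or C-alpha tables) generated from bootstrap-resampled
    data; member i of the light ensemble is paired with member i of the
    dark ensemble, the per-residue C-alpha separation computed for each
    pair, and the sample standard deviation over replicates returned as
    {(chain, residue number): std}.
    """
    from .structures import ca_table

    if len(light_ensemble) != len(dark_ensemble) or len(light_ensemble) < 2:
        raise ValueError("ensembles must be paired with >= 2 members each")
    tables_l = [m if isinstance(m, dict) else ca_table(m) for m in light_ensemble]
    tables_d = [m if isinstance(m, dict) else ca_table(m) for m in dark_ensemble]
    keys = set(tables_l[0])
    for t in tables_l + tables_d:
        if set(t) != keys:
            raise ValueError("ensemble members differ in residue topology")
    keys = sorted(keys)
    seps = np.array(
        [
            [np.linalg.norm(tl[k] - td[k]) for k in keys]
            for tl, td in zip(tables_l, tables_d)
        ]
    )
    stds = np.std(seps, axis=0, ddof=1)
    return dict(zip(keys, stds))
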