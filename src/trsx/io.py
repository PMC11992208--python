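"""File readers and writers, plus unit-cell-based dataset filtering.

Formats:

* spectra — CSV/TSV, first column the wavelength (nm), header row the
  pump-probe delays (ms), cells the difference absorbance;
* reflections — whitespace text ``h k l F [sigF]`` or MTZ (via gemmi);
* phases — whitespace text ``h k l phi`` (degrees);
* observations — ``h k l F`` with repeated lines per index;
* maps — CCP4/MRC (via gemmi);
* models — PDB/mmCIF by extension (via gemmi);
* profiles — CSV ``chain,residue,pos_amp,neg_amp`` (sequence
  projection) or ``chain,residue,displacement`` (displacements).

Malformed text lines are reported with their line number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import gemmi

from .bootstrap import ObservationSet
from .diffmap import PhaseSet, RealSpaceMap, ReflectionSet
from .kinetics import SpectralSeries
from .projection1d import SequenceProfile
from .structures import DisplacementProfile

__all__ = [
    "read_spectra_csv", "write_spectra_csv",
    "read_hkl", "write_hkl", "read_phases", "write_phases",
    "read_observations", "write_observations",
    "read_mtz", "write_mtz",
    "read_ccp4", "write_ccp4",
    "read_structure", "write_structure",
    "read_sequence_profile", "write_sequence_profile",
    "write_displacement_profile",
    "filter_by_cell",
]


# ---------------------------------------------------------------------------
# spectra


def read_spectra_csv(path, sep: str = ",") -> SpectralSeries:
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(f"{path}: expected wavelength column plus delay columns")
    wavelengths = df.iloc[:, 0].to_numpy(dtype=float)
    try:
        delays = np.array([float(c) for c in df.columns[1:]])
    except ValueError as e:
        raise ValueError(f"{path}: delay header is not numeric: {e}") from None
    D = df.iloc[:, 1:].to_numpy(dtype=float)
    return SpectralSeries(wavelengths, delays, D)


def write_spectra_csv(series: SpectralSeries, path, sep: str = ",") -> None:
    df = pd.DataFrame(series.D, columns=[f"{t:.10g}" for t in series.delays])
    df.insert(0, "wavelength_nm", series.wavelengths)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# reflection text formats


def _parse_columns(path, n_min: int, n_max: int):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if not (n_min <= len(parts) <= n_max):
                raise ValueError(f"{path}:{ln}: expected {n_min}-{n_max} fields, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric field in '{s}'") from None
    if not rows:
        raise ValueError(f"{path}: no data lines")
    return rows


def read_hkl(path, cell) -> ReflectionSet:
    """Read ``h k l F [sigF]`` text; ``cell`` is six parameters or a UnitCell."""
    rows = _parse_columns(path, 4, 5)
    arr = np.array([r + [np.nan] * (5 - len(r)) for r in rows])
    hkl = arr[:, :3].astype(int)
    sig = arr[:, 4]
    return ReflectionSet(cell, hkl, arr[:, 3],
                         sigma_amp=None if np.all(np.isnan(sig)) else sig)


def write_hkl(refl: ReflectionSet, path) -> None:
    with open(path, "w") as fh:
        for i, (h, k, l) in enumerate(refl.hkl):
            line = f"{h:5d} {k:5d} {l:5d} {refl.amplitude[i]:14.6f}"
            if refl.sigma_amp is not None:
                line += f" {refl.sigma_amp[i]:12.6f}"
            fh.write(line + "\n")


def read_phases(path) -> PhaseSet:
    rows = _parse_columns(path, 4, 4)
    arr = np.array(rows)
    return PhaseSet(arr[:, :3].astype(int), arr[:, 3])


def write_phases(phases: PhaseSet, path) -> None:
    with open(path, "w") as fh:
        for (h, k, l), p in zip(phases.hkl, phases.phase_deg):
            fh.write(f"{h:5d} {k:5d} {l:5d} {p:12.5f}\n")


def read_observations(path, cell) -> ObservationSet:
    rows = _parse_columns(path, 4, 4)
    arr = np.array(rows)
    return ObservationSet(gemmi.UnitCell(*cell) if not isinstance(cell, gemmi.UnitCell) else cell,
                          arr[:, :3].astype(int), arr[:, 3])


def write_observations(obs: ObservationSet, path) -> None:
    with open(path, "w") as fh:
        for (h, k, l), v in zip(obs.hkl, obs.values):
            fh.write(f"{h:5d} {k:5d} {l:5d} {v:14.6f}\n")


# ---------------------------------------------------------------------------
# MTZ


def write_mtz(refl: ReflectionSet, path, phases: PhaseSet | None = None) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.cell = refl.cell
    mtz.spacegroup = gemmi.SpaceGroup("P 1")
    mtz.add_dataset("data")
    mtz.add_column("F", "F")
    mtz.add_column("SIGF", "Q")
    cols = [refl.hkl.astype(float), refl.amplitude[:, None]]
    sig = refl.sigma_amp if refl.sigma_amp is not None else np.zeros_like(refl.amplitude)
    cols.append(sig[:, None])
    if phases is not None:
        mtz.add_column("PHI", "P")
        pdict = phases.to_dict()
        cols.append(np.array([[pdict[tuple(h)]] for h in refl.hkl]))
    mtz.set_data(np.hstack(cols))
    mtz.write_to_file(str(path))


def read_mtz(path):
    """Returns (ReflectionSet, PhaseSet or None) from columns F/SIGF[/PHI]."""
    mtz = gemmi.Mtz()
    mtz = gemmi.read_mtz_file(str(path))
    hkl = np.array(mtz.make_miller_array(), dtype=int)
    f = mtz.column_with_label("F")
    if f is None:
        raise ValueError(f"{path}: no F column")
    sig = mtz.column_with_label("SIGF")
    refl = ReflectionSet(
        mtz.cell, hkl, np.array(f),
        sigma_amp=np.array(sig) if sig is not None else None,
    )
    phi = mtz.column_with_label("PHI")
    phases = PhaseSet(hkl, np.array(phi)) if phi is not None else None
    return refl, phases


# ---------------------------------------------------------------------------
# maps and models


def write_ccp4(rsmap: RealSpaceMap, path) -> None:
    grid = gemmi.FloatGrid(np.asarray(rsmap.values, dtype=np.float32))
    grid.set_unit_cell(rsmap.cell)
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_ccp4(path) -> RealSpaceMap:
    ccp4 = gemmi.read_ccp4_map(str(path))
    return RealSpaceMap(ccp4.grid.unit_cell, np.array(ccp4.grid, dtype=float))


def read_structure(path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def write_structure(structure: gemmi.Structure, path) -> None:
    path = str(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        structure.make_mmcif_document().write_file(path)
    else:
        structure.write_pdb(path)


# ---------------------------------------------------------------------------
# profiles


def write_sequence_profile(profile: SequenceProfile, path) -> None:
    df = pd.DataFrame(
        {
            "chain": [k[0] for k in profile.keys],
            "residue": [k[1] for k in profile.keys],
            "pos_amp": profile.pos_amp,
            "neg_amp": profile.neg_amp,
        }
    )
    df.to_csv(path, index=False)


def read_sequence_profile(path, threshold_sigma: float = np.nan,
                          cutoff_A: float = np.nan) -> SequenceProfile:
    df = pd.read_csv(path)
    return SequenceProfile(
        keys=list(zip(df["chain"], df["residue"])),
        pos_amp=df["pos_amp"].to_numpy(float),
        neg_amp=df["neg_amp"].to_numpy(float),
        threshold_sigma=threshold_sigma,
        cutoff_A=cutoff_A,
    )


def write_displacement_profile(profile: DisplacementProfile, path) -> None:
    df = pd.DataFrame(
        {
            "chain": [k[0] for k in profile.keys],
            "residue": [k[1] for k in profile.keys],
            "displacement_A": profile.displacement,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# unit-cell filtering


def filter_by_cell(records, target, length_tol: float = 0.015,
                   angle_tol_deg: float = 1.5):
    """Split cell records into (kept, rejected) around a target cell.

    ``records`` is a sequence of six-parameter cells (a, b, c in A;
    angles in degrees).  A record is kept when every axis is within the
    fractional ``length_tol`` of the target and every angle within
    ``angle_tol_deg``.  Serial crystallography data often mixes crystal
    forms; imposing the cell of the well-diffracting form selects the
    usable subset.
    """
    if length_tol < 0 or angle_tol_deg < 0:
        raise ValueError("tolerances must be non-negative")
    target = np.asarray(target, dtype=float)
    kept, rejected = [], []
    for rec in records:
        r = np.asarray(rec, dtype=float)
        if np.any(r[:3] <= 0) or np.any((r[3:] <= 0) | (r[3:] >= 180)):
            raise ValueError(f"invalid cell record {rec}")
        ok = np.all(np.abs(r[:3] - target[:3]) <= length_tol * target[:3]) and np.all(
            np.abs(r[3:] - target[3:]) <= angle_tol_deg
        )
        (kept if ok else rejected).append(rec)
    return kept, rejected
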