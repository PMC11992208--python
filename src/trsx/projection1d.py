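"""Projection of 3D difference density onto the protein sequence.

Every grid point whose |density| exceeds a sigma threshold and which
lies within a cutoff radius of the model is attributed to the residue of
its nearest atom; positive and negative amplitudes are accumulated
separately per residue.  The resulting 1D profile makes light-induced
density changes comparable across time points (via Pearson correlation
of the concatenated positive/negative vectors) and across proteins (via
mean amplitudes over named helix regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .diffmap import RealSpaceMap, _frac_matrix, _orth_matrix

__all__ = [
    "ModelAtom",
    "SequenceProfile",
    "RegionDefinition",
    "SRII_HELICES",
    "SRII_REGIONS",
    "atoms_from_structure",
    "atoms_from_toy",
    "project_to_sequence",
    "profile_correlation",
    "region_mean_amplitude",
]


@dataclass
class ModelAtom:
    """Minimal atom record for density assignment (fractional coordinates)."""

    frac: tuple
    chain: str
    resid: int
    name: str
    element: str
    serial: int


# Transmembrane helix boundaries of sensory rhodopsin II (model numbering)
SRII_HELICES = {
    "A": (3, 26),
    "B": (33, 56),
    "C": (70, 92),
    "D": (94, 118),
    "E": (122, 150),
    "F": (153, 181),
    "G": (189, 219),
}

# Regions over which mean difference-density amplitudes are tracked in time:
# extracellular helix C, extracellular helices D/E, cytoplasmic helix F plus
# the F/G loop, and the mid-portion of helix G.
SRII_REGIONS = {
    "helix_C_extracellular": (71, 81),
    "helix_DE_extracellular": (118, 124),
    "helix_F_FG_loop": (143, 171),
    "helix_G_mid": (197, 213),
}


@dataclass
class RegionDefinition:
    label: str
    first: int
    last: int

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError("region first residue must be <= last")


@dataclass
class SequenceProfile:
    """Per-residue positive/negative difference-density amplitude."""

    keys: list               # (chain, residue number), sorted; one per residue
    pos_amp: np.ndarray
    neg_amp: np.ndarray
    threshold_sigma: float
    cutoff_A: float
    dropped_amplitude: float = 0.0  # above-threshold density beyond the cutoff

    def residue_ids(self) -> np.ndarray:
        return np.array([k[1] for k in self.keys])

    def total(self) -> np.ndarray:
        return self.pos_amp + self.neg_amp


def atoms_from_structure(structure: gemmi.Structure,
                         cell: gemmi.UnitCell | None = None) -> list[ModelAtom]:
    """Flatten a gemmi structure into ModelAtom records (hydrogens dropped)."""
    cell = cell or structure.cell
    out = []
    serial = 0
    for model in structure:
        for chain in model:
            for res in chain:
                for atom in res:
                    serial += 1
                    if atom.element.is_hydrogen():
                        continue
                    f = cell.fractionalize(atom.pos)
                    out.append(
                        ModelAtom(
                            frac=(f.x, f.y, f.z),
                            chain=chain.name,
                            resid=res.seqid.num,
                            name=atom.name,
                            element=atom.element.name,
                            serial=atom.serial or serial,
                        )
                    )
        break
    return out


def atoms_from_toy(toy) -> list[ModelAtom]:
    """ModelAtom records for a Gaussian-atom toy crystal."""
    return [
        ModelAtom(
            frac=tuple(a.frac), chain=a.chain, resid=a.resid,
            name=a.name, element=a.element, serial=a.serial,
        )
        for a in toy.atoms
    ]


def project_to_sequence(
    rsmap: RealSpaceMap,
    atoms: list[ModelAtom],
    threshold_sigma: float = 3.0,
    cutoff_A: float = 2.0,
) -> SequenceProfile:
    """Assign above-threshold difference density to residues.

    Each grid point with |value| >= threshold * sigma is attributed to
    the residue of its nearest non-hydrogen atom (minimum-image
    distance; exact ties go to the lowest atom serial) provided that
    distance is within ``cutoff_A``; |value| is accumulated into the
    residue's positive or negative amplitude by sign.  Above-threshold
    density farther than the cutoff from any atom is summed into
    ``dropped_amplitude``, so assigned + dropped equals the total
    above-threshold amplitude exactly.
    """
    atoms = [a for a in atoms if a.element.upper() not in ("H", "D")]
    if not atoms:
        raise ValueError("model contains no non-hydrogen atoms")
    if threshold_sigma <= 0:
        raise ValueError("threshold must be positive")
    atoms = sorted(atoms, key=lambda a: a.serial)  # argmin tie -> lowest serial
    keys = sorted({(a.chain, a.resid) for a in atoms})
    key_index = {k: i for i, k in enumerate(keys)}
    pos_amp = np.zeros(len(keys))
    neg_amp = np.zeros(len(keys))

    v = rsmap.values
    sigma = rsmap.sigma
    dropped = 0.0
    if sigma > 0:
        n = np.array(rsmap.shape)
        mask = np.abs(v) >= threshold_sigma * sigma
        ijk = np.argwhere(mask)
        if len(ijk):
            vals = v[mask]
            frac_pts = ijk / n
            atom_frac = np.array([a.frac for a in atoms])
            M = _orth_matrix(rsmap.cell)
            # chunk over grid points to bound the (points x atoms) matrix
            nearest = np.empty(len(ijk), dtype=int)
            mind = np.empty(len(ijk))
            step = max(1, 2_000_000 // max(len(atoms), 1))
            for lo in range(0, len(ijk), step):
                sl = slice(lo, lo + step)
                d = frac_pts[sl, None, :] - atom_frac[None, :, :]
                d -= np.round(d)
                cart = d @ M.T
                dist = np.sqrt(np.sum(cart * cart, axis=2))
                nearest[sl] = np.argmin(dist, axis=1)
                mind[sl] = dist[np.arange(dist.shape[0]), nearest[sl]]
            within = mind <= cutoff_A
            dropped = float(np.sum(np.abs(vals[~within])))
            for a_idx, val in zip(nearest[within], vals[within]):
                r = key_index[(atoms[a_idx].chain, atoms[a_idx].resid)]
                if val >= 0:
                    pos_amp[r] += val
                else:
                    neg_amp[r] += -val

    return SequenceProfile(
        keys=keys,
        pos_amp=pos_amp,
        neg_amp=neg_amp,
        threshold_sigma=threshold_sigma,
        cutoff_A=cutoff_A,
        dropped_amplitude=dropped,
    )


def profile_correlation(p1: SequenceProfile, p2: SequenceProfile) -> float | None:
    """Pearson correlation of two profiles' concatenated (pos, neg) vectors.

    Returns None (undefined) when either concatenated vector has zero
    variance.
    """
    if p1.keys != p2.keys:
        raise ValueError("profiles are on different residue axes")
    a = np.concatenate([p1.pos_amp, p1.neg_amp])
    b = np.concatenate([p2.pos_amp, p2.neg_amp])
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def region_mean_amplitude(profile: SequenceProfile, region) -> float:
    """Mean of (pos + neg) amplitude over an inclusive residue range.

    ``region`` is a :class:`RegionDefinition` or a (first, last) pair.
    """
    if isinstance(region, RegionDefinition):
        first, last = region.first, region.last
    else:
        first, last = region
    ids = profile.residue_ids()
    mask = (ids >= first) & (ids <= last)
    if not np.any(mask):
        raise ValueError(f"no profile residues in region {first}..{last}")
    return float(profile.total()[mask].mean())
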