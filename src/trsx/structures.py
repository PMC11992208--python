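"""Superposition and displacement analysis of paired dark/light models.

Models are :class:`gemmi.Structure` objects (read from PDB or mmCIF via
:mod:`trsx.io`).  C-alpha atoms are matched strictly by (chain name,
residue number); unmatched residues are skipped and counted rather than
raised, since paired depositions routinely model different residue
ranges.

Superposition is the classic Kabsch least-squares rigid fit with a
proper rotation enforced.  Displacement profiles are per-residue
C-alpha distances, optionally after a global superposition: conformers
refined within one crystal frame are compared without superposition,
separate depositions with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "SuperpositionResult",
    "DisplacementProfile",
    "ca_table",
    "superpose_ca_rmsd",
    "conformer_split",
    "per_residue_displacement",
    "region_mean_displacement",
]


def ca_table(structure: gemmi.Structure, altloc: str | None = None) -> dict:
    """(chain, residue number) -> C-alpha position (3-array).

    When a residue has alternate conformers, ``altloc`` selects which to
    take (blank-altloc atoms always qualify); with ``altloc=None`` the
    first C-alpha encountered wins.
    """
    out: dict[tuple, np.ndarray] = {}
    for model in structure:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.name != "CA":
                        continue
                    if altloc is not None and atom.altloc not in ("", "\x00", altloc):
                        continue
                    key = (chain.name, res.seqid.num)
                    if key not in out:
                        out[key] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    return out


def _matched_coords(a, b, selection=None):
    ta = a if isinstance(a, dict) else ca_table(a)
    tb = b if isinstance(b, dict) else ca_table(b)
    keys = sorted(set(ta) & set(tb))
    if selection is not None:
        sel = set(selection)
        keys = [k for k in keys if k[1] in sel]
    n_unmatched = len(set(ta) ^ set(tb))
    if not keys:
        raise ValueError("no matched C-alpha pairs")
    X = np.array([ta[k] for k in keys])
    Y = np.array([tb[k] for k in keys])
    return keys, X, Y, n_unmatched


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3), proper
    translation: np.ndarray   # (3,), applied as R @ x + t
    rmsd: float               # A over matched pairs
    n_matched: int
    n_unmatched: int
    degenerate: bool          # matched set essentially collinear

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(X: np.ndarray, Y: np.ndarray):
    """Proper rotation R and translation t minimising ||R X + t - Y||."""
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    # collinearity: second singular value of the centred cloud ~ 0
    sv = np.linalg.svd(X - xc, compute_uv=False)
    degenerate = bool(sv[1] < 1e-8 * max(sv[0], 1.0))
    return R, t, degenerate


def superpose_ca_rmsd(model_a, model_b, selection=None) -> SuperpositionResult:
    """Least-squares rigid superposition of A onto B over matched C-alphas.

    ``selection`` restricts the match to the given residue numbers.
    Requires >= 3 matched pairs; a collinear matched set is flagged via
    ``degenerate`` (the rotation about the line is then arbitrary).
    """
    keys, X, Y, n_unmatched = _matched_coords(model_a, model_b, selection)
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} matched C-alpha pairs (need >= 3)")
    R, t, degenerate = _kabsch(X, Y)
    moved = X @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd, len(keys), n_unmatched, degenerate)


def conformer_split(structure: gemmi.Structure, tag_light: str = "B",
                    tag_dark: str = "A"):
    """Split a partial-occupancy model into dark and light submodels.

    Atoms carrying the dark altloc tag (or no tag) form the dark
    submodel; likewise for light.  A structure with alternate conformers
    matching neither tag is rejected.
    """
    tags = set()
    for model in structure:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "\x00"):
                        tags.add(atom.altloc)
    if tags and not (tags & {tag_light, tag_dark}):
        raise ValueError(
            f"model has conformer tags {sorted(tags)}, neither "
            f"'{tag_dark}' (dark) nor '{tag_light}' (light)"
        )

    def keep_only(tag: str) -> gemmi.Structure:
        st = structure.clone()
        for model in st:
            for chain in model:
                for res in chain:
                    for i in reversed(range(len(res))):
                        alt = res[i].altloc
                        if alt not in ("", "\x00") and alt != tag:
                            del res[i]
        return st

    return keep_only(tag_dark), keep_only(tag_light)


@dataclass
class DisplacementProfile:
    """Per-residue C-alpha displacement (A) between paired models."""

    keys: list                # (chain, residue number), sorted
    displacement: np.ndarray  # (n,), >= 0
    n_unmatched: int = 0

    def residue_ids(self) -> np.ndarray:
        return np.array([k[1] for k in self.keys])


def per_residue_displacement(dark, light, superpose: bool = False) -> DisplacementProfile:
    """|CA_light - CA_dark| per residue, optionally after global superposition.

    With ``superpose=True`` the light model is first rigidly fitted onto
    the dark one over all matched C-alphas, removing any overall
    rotation/translation between the two frames.
    """
    keys, Xd, Xl, n_unmatched = _matched_coords(dark, light)
    if superpose:
        R, t, _ = _kabsch(Xl, Xd)
        Xl = Xl @ R.T + t
    disp = np.sqrt(np.sum((Xl - Xd) ** 2, axis=1))
    return DisplacementProfile(keys=keys, displacement=disp, n_unmatched=n_unmatched)


def region_mean_displacement(profile: DisplacementProfile, first_id: int,
                             last_id: int) -> float:
    """Mean displacement over the inclusive residue-number range."""
    ids = profile.residue_ids()
    mask = (ids >= first_id) & (ids <= last_id)
    if not np.any(mask):
        raise ValueError(f"no profile residues in range {first_id}..{last_id}")
    return float(profile.displacement[mask].mean())
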