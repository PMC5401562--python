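"""Geometric measurements on trimeric channel structures.

Covers the measurements that characterize the transmembrane architecture of
a C3-symmetric homotrimer:

* helix axes by principal-component fit of C-alpha coordinates (kinked
  helices are handled by fitting each sub-segment, e.g. M2a/M2b,
  independently);
* the trimer C3 axis as the rotation axis of the optimal least-squares
  120-degree superposition between two chains;
* helix tilt angles eta = angle(helix axis, C3 axis), folded into [0, 90]
  degrees;
* three-class labeling of a pore-radius profile -- constricted (< 1.15 A,
  narrower than a dehydrated K+ ion), intermediate (between 1.15 and
  2.30 A) and wide (> 2.30 A, passes a partially hydrated ion) -- plus the
  constriction sites (gates) as maximal constricted runs;
* coordination contacts around an ion site within a distance cutoff.

Coordinates are read from PDB or mmCIF via gemmi; everything is in
Angstroms and source-file residue numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "HelixSpan",
    "read_structure",
    "fit_helix_axis",
    "trimer_c3_axis",
    "tilt_angle",
    "tilt_table",
    "classify_pore_profile",
    "coordination_contacts",
    "CONSTRICTED_RADIUS",
    "WIDE_RADIUS",
]

CONSTRICTED_RADIUS = 1.15  # A; below this a run counts as a gate
WIDE_RADIUS = 2.30  # A


@dataclass
class StructureModel:
    """Flat atom table of one model: one row per atom, coordinates in A."""

    atoms: pd.DataFrame
    source_id: str = ""

    _REQUIRED = ("atom_name", "residue_name", "residue_number", "chain_id", "element", "x", "y", "z")

    def __post_init__(self):
        missing = set(self._REQUIRED) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def chain_ids(self) -> list:
        return sorted(self.atoms["chain_id"].unique())

    def ca_coords(self, chain_id: str, first: int | None = None, last: int | None = None):
        """C-alpha coordinates (and residue numbers) of a chain or span."""
        df = self.atoms
        sel = (df["chain_id"] == chain_id) & (df["atom_name"] == "CA")
        if first is not None:
            sel &= df["residue_number"] >= first
        if last is not None:
            sel &= df["residue_number"] <= last
        sub = df[sel].sort_values("residue_number")
        return sub[["x", "y", "z"]].to_numpy(dtype=float), sub["residue_number"].to_numpy()


def read_structure(path, source_id: str | None = None) -> StructureModel:
    """Read the first model of a PDB or mmCIF file into a StructureModel."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                rows.append(
                    (
                        atom.name,
                        residue.name,
                        residue.seqid.num,
                        chain.name,
                        atom.element.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    atoms = pd.DataFrame(rows, columns=list(StructureModel._REQUIRED))
    return StructureModel(atoms=atoms, source_id=source_id or Path(str(path)).stem)


@dataclass
class HelixSpan:
    """A (sub-)helix defined by chain and residue range, with its fitted axis."""

    label: str
    chain_id: str
    first: int
    last: int
    axis: np.ndarray = field(default=None)
    centroid: np.ndarray = field(default=None)


def fit_helix_axis(span_coords, reference_axis=(0.0, 0.0, 1.0)):
    """Principal axis of a C-alpha cloud: (unit vector, centroid).

    The axis is the dominant right-singular vector of the centered
    coordinates, with its sign normalized to a positive component along
    ``reference_axis`` (the C3/membrane-normal direction), so helices
    running N->C "down" report the same axis as their "up" neighbours.
    """
    coords = np.asarray(span_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 5:
        raise ValueError("need at least 5 C-alpha positions")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate coordinates: no principal direction")
    axis = vt[0]
    ref = np.asarray(reference_axis, dtype=float)
    if float(axis @ ref) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def trimer_c3_axis(structure: StructureModel, chains=("A", "B", "C"), min_matched: int = 50):
    """C3 symmetry axis of a trimer: (unit vector, point on axis).

    Computed as the rotation axis of the least-squares rigid superposition
    mapping the first chain onto the second (Kabsch), which for a
    C3-symmetric assembly is a 120-degree rotation about the symmetry axis.
    The first->third superposition serves as a consistency check: a warning
    is raised if the two axes differ by more than 2 degrees, or if the
    rotation angle strays far from 120 degrees.  The returned point is the
    joint centroid of the matched chains, which lies on the axis for a
    symmetric trimer.
    """
    if len(chains) != 3:
        raise ValueError("exactly three chain ids required")

    def matched_ca(c1, c2):
        xyz1, num1 = structure.ca_coords(c1)
        xyz2, num2 = structure.ca_coords(c2)
        common, i1, i2 = np.intersect1d(num1, num2, return_indices=True)
        if len(common) < min_matched:
            raise ValueError(
                f"chains {c1}/{c2} share only {len(common)} matched C-alphas (< {min_matched})"
            )
        return xyz1[i1], xyz2[i2]

    def rotation_axis(c1, c2):
        a, b = matched_ca(c1, c2)
        rot, _ = Rotation.align_vectors(b - b.mean(axis=0), a - a.mean(axis=0))
        rotvec = rot.as_rotvec()
        angle = np.degrees(np.linalg.norm(rotvec))
        return rotvec / np.linalg.norm(rotvec), angle

    axis_ab, angle_ab = rotation_axis(chains[0], chains[1])
    if not 100.0 <= angle_ab <= 140.0:
        warnings.warn(
            f"{chains[0]}->{chains[1]} superposition rotates by {angle_ab:.1f} deg, not ~120"
        )
    axis_ac, _ = rotation_axis(chains[0], chains[2])
    cross_angle = tilt_angle(axis_ab, axis_ac)
    if cross_angle > 2.0:
        warnings.warn(
            f"C3 axes from {chains[0]}->{chains[1]} and {chains[0]}->{chains[2]} "
            f"superpositions differ by {cross_angle:.2f} deg"
        )

    ca_all = [structure.ca_coords(c)[0] for c in chains]
    point = np.vstack(ca_all).mean(axis=0)
    # orient consistently: positive z if possible (arbitrary but deterministic)
    if axis_ab[2] < 0 or (axis_ab[2] == 0 and axis_ab[np.argmax(np.abs(axis_ab))] < 0):
        axis_ab = -axis_ab
    return axis_ab, point


def tilt_angle(helix_axis, c3_axis) -> float:
    """Angle eta between two axes, folded into [0, 90] degrees.

    Axes are directionless, so antiparallel vectors give 0.
    """
    a = np.asarray(helix_axis, dtype=float)
    b = np.asarray(c3_axis, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length axis vector")
    cosang = abs(float(a @ b)) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def tilt_table(structure: StructureModel, spans, chains=("A", "B", "C")) -> pd.DataFrame:
    """Tilt angle per helix span versus the trimer C3 axis.

    ``spans`` is an iterable of HelixSpan (or (label, chain, first, last)
    tuples).  Returns a DataFrame (helix, chain, first, last, eta_deg).
    """
    c3, _ = trimer_c3_axis(structure, chains=chains)
    rows = []
    for sp in spans:
        if not isinstance(sp, HelixSpan):
            sp = HelixSpan(label=sp[0], chain_id=sp[1], first=int(sp[2]), last=int(sp[3]))
        coords, _ = structure.ca_coords(sp.chain_id, sp.first, sp.last)
        axis, centroid = fit_helix_axis(coords, reference_axis=c3)
        sp.axis, sp.centroid = axis, centroid
        rows.append((sp.label, sp.chain_id, sp.first, sp.last, tilt_angle(axis, c3)))
    return pd.DataFrame(rows, columns=["helix", "chain", "first", "last", "eta_deg"])


def classify_pore_profile(profile: pd.DataFrame):
    """Label each pore-profile row and locate the constriction sites.

    ``profile`` needs columns ``z_A`` (strictly monotone axial coordinate)
    and ``radius_A`` (> 0).  Rows are labeled 'constricted' (radius
    < 1.15 A), 'wide' (> 2.30 A) or 'intermediate' (everything between,
    boundary values included -- the class bounds are strict inequalities).
    Returns (labeled profile copy, constriction table) where each
    constriction is a maximal constricted run with its axial extent and
    minimum radius.
    """
    if len(profile) == 0:
        raise ValueError("empty pore profile")
    z = profile["z_A"].to_numpy(dtype=float)
    r = profile["radius_A"].to_numpy(dtype=float)
    dz = np.diff(z)
    if len(z) > 1 and not (np.all(dz > 0) or np.all(dz < 0)):
        raise ValueError("axial coordinate must be strictly monotone")
    if np.any(r <= 0):
        raise ValueError("radii must be positive")

    labels = np.where(r < CONSTRICTED_RADIUS, "constricted", np.where(r > WIDE_RADIUS, "wide", "intermediate"))
    out = profile.copy()
    out["class"] = labels

    constricted = labels == "constricted"
    runs = []
    padded = np.concatenate([[False], constricted, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    for s, e in zip(starts, ends):
        seg_r = r[s:e]
        runs.append(
            {
                "z_start_A": float(min(z[s], z[e - 1])),
                "z_end_A": float(max(z[s], z[e - 1])),
                "min_radius_A": float(seg_r.min()),
                "z_at_min_A": float(z[s + int(np.argmin(seg_r))]),
                "n_points": int(e - s),
            }
        )
    return out, pd.DataFrame(runs, columns=["z_start_A", "z_end_A", "min_radius_A", "z_at_min_A", "n_points"])


def coordination_contacts(structure: StructureModel, center, cutoff: float) -> pd.DataFrame:
    """Non-hydrogen atoms within ``cutoff`` A of ``center`` (closed ball).

    Returns a DataFrame sorted by ascending distance with an atom identifier
    of the form ``chain/RES num/ATOM``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    c = np.asarray(center, dtype=float)
    df = structure.atoms[structure.atoms["element"] != "H"]
    d = np.linalg.norm(df[["x", "y", "z"]].to_numpy(dtype=float) - c, axis=1)
    keep = d <= cutoff
    ids = (
        df.loc[keep, "chain_id"]
        + "/"
        + df.loc[keep, "residue_name"]
        + " "
        + df.loc[keep, "residue_number"].astype(str)
        + "/"
        + df.loc[keep, "atom_name"]
    )
    out = pd.DataFrame({"atom": ids.to_numpy(), "distance_A": d[keep]})
    return out.sort_values("distance_A", kind="stable").reset_index(drop=True)
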