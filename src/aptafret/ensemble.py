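"""Rigid-body ensemble analysis of scaffolded fluorophore positions.

Given a set of conformational ensemble members — coordinate models each
containing a donor aptamer with its chromophore (DFHBI-1T-like ligand)
and an acceptor aptamer with its chromophore (HBC620-like ligand) — this
module reproduces the acceptor-frame alignment procedure used to assess
the positional precision of a scaffolded FRET pair:

1. every member is rigidly superposed onto a reference member using only
   the acceptor-ligand atoms, so the acceptor chromophores coincide
   while each member's internal donor-acceptor geometry is preserved;
2. per-member donor-acceptor chromophore-centre distances, per-
   fluorophore motion ranges (max pairwise centre displacement), and the
   maximum pairwise donor dipole rotation are summarized.

Chromophore centre = centroid of the ligand's non-hydrogen atoms; the
dipole proxy is the first principal axis of those atoms, sign-fixed by a
reference atom pair so that antiparallel flips of the eigenvector do not
masquerade as rotation.  The summary "range" (max − min distance) is the
headline positional-variability number; an unbiased statistical variance
of the distances is reported alongside under its own name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import DegenerateInputError, SelectorError

__all__ = [
    "LigandSelectors",
    "EnsembleMember",
    "RigidTransform",
    "PairGeometry",
    "read_members",
    "superpose",
    "align_on_acceptor",
    "pair_geometry",
]

#: residue-name aliases for the donor chromophore (DFHBI-1T-like);
#: chemical-component codes vary across depositions, so this is a set
DONOR_RESNAMES = frozenset({"DFB", "DF1", "DFH", "9GV"})
#: aliases for the acceptor chromophore (HBC620-like)
ACCEPTOR_RESNAMES = frozenset({"HBC", "HB6", "H2C"})


@dataclass(frozen=True)
class LigandSelectors:
    """Residue-name sets identifying the two chromophores."""

    donor: frozenset = DONOR_RESNAMES
    acceptor: frozenset = ACCEPTOR_RESNAMES

    @classmethod
    def from_names(cls, donor: str, acceptor: str) -> "LigandSelectors":
        return cls(donor=frozenset({donor}), acceptor=frozenset({acceptor}))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t."""

    rotation: np.ndarray  # 3x3, orthogonal, det +1
    translation: np.ndarray  # Å

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation has det != +1 (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class EnsembleMember:
    """One rigid placement of the donor and acceptor aptamer models.

    ``coords`` holds every atom; ``donor_idx``/``acceptor_idx`` index the
    non-hydrogen ligand atoms, ordered by (residue name, atom name) so
    that correspondence across members is positional.
    """

    label: str
    coords: np.ndarray  # (n_atoms, 3) Å
    atom_names: list[str]
    residue_names: list[str]
    elements: list[str]
    donor_idx: np.ndarray
    acceptor_idx: np.ndarray

    @property
    def donor_ligand(self) -> np.ndarray:
        return self.coords[self.donor_idx]

    @property
    def acceptor_ligand(self) -> np.ndarray:
        return self.coords[self.acceptor_idx]

    @property
    def donor_centre(self) -> np.ndarray:
        return self.donor_ligand.mean(axis=0)

    @property
    def acceptor_centre(self) -> np.ndarray:
        return self.acceptor_ligand.mean(axis=0)

    @property
    def pair_distance(self) -> float:
        return float(np.linalg.norm(self.donor_centre - self.acceptor_centre))

    def transformed(self, tf: RigidTransform) -> "EnsembleMember":
        return replace(self, coords=tf.apply(self.coords))

    def donor_dipole(self, ref_atoms: tuple[str, str] | None = None) -> np.ndarray:
        """Unit principal axis of the donor ligand, sign-fixed.

        The sign is chosen so the axis points from the first to the
        second reference atom (defaults: first and last ligand atoms in
        correspondence order).
        """
        pts = self.donor_ligand
        centred = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9) < 1 or len(pts) < 2:
            raise DegenerateInputError("donor ligand has no extent; dipole undefined")
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
        names = [self.atom_names[i] for i in self.donor_idx]
        if ref_atoms is None:
            a, b = 0, len(names) - 1
        else:
            try:
                a, b = names.index(ref_atoms[0]), names.index(ref_atoms[1])
            except ValueError as exc:
                raise SelectorError(
                    f"dipole reference atoms {ref_atoms} not in donor ligand"
                ) from exc
        ref = pts[b] - pts[a]
        if axis @ ref < 0:
            axis = -axis
        return axis / np.linalg.norm(axis)


@dataclass
class PairGeometry:
    """Summary of fluorophore geometry across an (aligned) ensemble."""

    distances: np.ndarray  # per member, Å
    labels: list[str]
    donor_dipoles: np.ndarray  # per member, unit vectors
    donor_motion_range: float  # max pairwise donor-centre distance, Å
    acceptor_motion_range: float
    max_dipole_angle_deg: float

    @property
    def min_distance(self) -> float:
        return float(self.distances.min())

    @property
    def max_distance(self) -> float:
        return float(self.distances.max())

    @property
    def distance_range(self) -> float:
        """Max − min distance: the headline positional-variability number."""
        return self.max_distance - self.min_distance

    @property
    def distance_variance(self) -> float:
        """Unbiased statistical variance of the distances (Å²)."""
        if len(self.distances) < 2:
            return 0.0
        return float(np.var(self.distances, ddof=1))


def _collect_member(
    structure: gemmi.Structure, selectors: LigandSelectors, label: str
) -> EnsembleMember:
    coords, atom_names, res_names, elements = [], [], [], []
    donor_keys, acceptor_keys = [], []
    model = structure[0]
    i = 0
    for chain in model:
        for res in chain:
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                atom_names.append(atom.name)
                res_names.append(res.name)
                elements.append(atom.element.name)
                if atom.element.name != "H":
                    if res.name in selectors.donor:
                        donor_keys.append(((res.name, atom.name), i))
                    elif res.name in selectors.acceptor:
                        acceptor_keys.append(((res.name, atom.name), i))
                i += 1
    for role, keys, sel in (
        ("donor", donor_keys, selectors.donor),
        ("acceptor", acceptor_keys, selectors.acceptor),
    ):
        if not keys:
            raise SelectorError(
                f"{label}: no {role} ligand atoms matched residue names {sorted(sel)}"
            )
    donor_idx = np.array([i for _, i in sorted(donor_keys)])
    acceptor_idx = np.array([i for _, i in sorted(acceptor_keys)])
    return EnsembleMember(
        label=label,
        coords=np.asarray(coords, dtype=float),
        atom_names=atom_names,
        residue_names=res_names,
        elements=elements,
        donor_idx=donor_idx,
        acceptor_idx=acceptor_idx,
    )


def read_members(
    paths: Sequence[str | Path], selectors: LigandSelectors | None = None
) -> list[EnsembleMember]:
    """Read PDB/mmCIF ensemble members and identify both ligands.

    Atom correspondence across members is by (residue name, atom name);
    members whose ligand atom sets differ are rejected.
    """
    selectors = selectors or LigandSelectors()
    members = []
    for path in paths:
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        members.append(_collect_member(st, selectors, Path(path).name))
    for attr in ("donor_idx", "acceptor_idx"):
        ref = members[0]
        ref_key = [
            (ref.residue_names[i], ref.atom_names[i]) for i in getattr(ref, attr)
        ]
        for m in members[1:]:
            key = [(m.residue_names[i], m.atom_names[i]) for i in getattr(m, attr)]
            if key != ref_key:
                raise SelectorError(
                    f"{m.label}: {attr.split('_')[0]} ligand atoms do not "
                    f"correspond 1:1 with {ref.label}"
                )
    return members


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns the proper rigid transform minimizing the RMSD between the
    transformed mobile points and the reference, plus that RMSD.  A
    determinant guard excludes reflections.  Requires >= 3 non-collinear
    corresponded points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(f"point sets differ in shape: {mob.shape} vs {ref.shape}")
    if mob.shape[0] < 3:
        raise DegenerateInputError("need at least 3 corresponded points")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateInputError("mobile points are collinear; rotation ill-posed")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    tf = RigidTransform(rotation=rot, translation=trans)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(mob) - ref) ** 2, axis=1))))
    return tf, rmsd


def align_on_acceptor(
    members: Sequence[EnsembleMember], reference: int | EnsembleMember = 0
) -> list[EnsembleMember]:
    """Superpose every member's acceptor ligand onto the reference's.

    Each member receives one rigid transform applied to all of its atoms,
    so internal donor-acceptor geometry is untouched while the acceptor
    chromophores are brought into a common frame.
    """
    ref = members[reference] if isinstance(reference, int) else reference
    aligned = []
    for m in members:
        tf, _ = superpose(m.acceptor_ligand, ref.acceptor_ligand)
        aligned.append(m.transformed(tf))
    return aligned


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())


def pair_geometry(
    members: Sequence[EnsembleMember],
    dipole_ref_atoms: tuple[str, str] | None = None,
) -> PairGeometry:
    """Distance, motion-range and dipole-rotation summary of an ensemble.

    Call on members already placed in a common frame (see
    :func:`align_on_acceptor`); motion ranges are frame-dependent,
    per-member distances are not.
    """
    if len(members) == 0:
        raise DegenerateInputError("empty ensemble")
    distances = np.array([m.pair_distance for m in members])
    donor_centres = np.array([m.donor_centre for m in members])
    acceptor_centres = np.array([m.acceptor_centre for m in members])
    dipoles = np.array([m.donor_dipole(dipole_ref_atoms) for m in members])
    max_angle = 0.0
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            cosang = float(np.clip(dipoles[i] @ dipoles[j], -1.0, 1.0))
            max_angle = max(max_angle, np.degrees(np.arccos(cosang)))
    return PairGeometry(
        distances=distances,
        labels=[m.label for m in members],
        donor_dipoles=dipoles,
        donor_motion_range=_max_pairwise_distance(donor_centres),
        acceptor_motion_range=_max_pairwise_distance(acceptor_centres),
        max_dipole_angle_deg=max_angle,
    )
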