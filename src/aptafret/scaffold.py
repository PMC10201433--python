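"""Coarse-grained 3-helix RNA origami tile model for aptamer placement.

Aptamer placements are written ``x,y-Bz-Pw`` (accepted with or without
the inner dash, e.g. ``1,3-B12P12``): the donor aptamer (Broccoli) sits
on helix ``x`` at ``z`` base pairs from the crossover, the acceptor
(Pepper) on helix ``y`` at ``w`` bp; a parenthesized negative offset,
``P(-34)``, places the stem on the opposite side of the crossover.

The tile is modelled as three ideal, parallel A-form helices in a plane:

* helix axes run along +x, spaced ``helix_spacing`` apart along +y
  (right-handed frame; the tile plane is xy);
* base pair ``k`` on a helix sits at ``k * rise_per_bp`` from the
  crossover reference (x = 0), with the helical phase advancing
  ``360 / bp_per_turn`` degrees per bp;
* an aptamer stem protrudes at the phase-determined azimuth of its
  placement; the chromophore sits at a fixed offset from the attachment
  point, expressed in the local (axial, radial, tangential) frame.  The
  axial direction points away from the crossover, i.e. follows the sign
  of the bp offset, so a stem grown on the far side of the crossover
  carries its aptamer outward on that side.

The default chromophore offsets are a one-time calibration of the
coarse-grained model against the in-silico placement distances of the
published three-helix designs (~2 nm for 1,3-B12P12, ~16 nm for
1,3-B12P(-34)); their magnitude (~19 Å from attachment to chromophore
centre) is consistent with the size of the scaffolded aptamers.  The
experimentally observed curvature of the central helix is not modelled;
the tile is ideal and planar.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DesignParseError
from .forster import DipolePair, fret_efficiency, kappa_squared

__all__ = [
    "Placement",
    "TileDesign",
    "TileParams",
    "Scaffold3D",
    "parse_design",
    "build_tile",
    "predict_distance",
    "predict_kappa_squared",
    "rank_designs",
]

_DESIGN_RE = re.compile(
    r"""^\s*
    (?P<hd>\d+)\s*,\s*(?P<ha>\d+)      # helix indices
    \s*-\s*B\s*(?P<zd>\(\s*-?\d+\s*\)|-?\d+)   # donor offset
    \s*-?\s*P\s*(?P<za>\(\s*-?\d+\s*\)|-?\d+)  # acceptor offset
    \s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class Placement:
    """One aptamer placement: helix index (1-3) and signed bp offset."""

    helix: int
    offset_bp: int

    def __post_init__(self) -> None:
        if self.helix not in (1, 2, 3):
            raise DesignParseError(f"helix index must be 1, 2 or 3, got {self.helix}")


@dataclass(frozen=True)
class TileDesign:
    """Parsed donor (Broccoli) and acceptor (Pepper) placements."""

    donor: Placement
    acceptor: Placement
    label: str = ""

    def swapped(self) -> "TileDesign":
        return TileDesign(donor=self.acceptor, acceptor=self.donor, label=self.label)


@dataclass(frozen=True)
class TileParams:
    """Geometry of the idealized tile and of the scaffolded fluorophores.

    ``rise_per_bp`` and ``bp_per_turn`` are A-form values as used by RNA
    origami design; ``helix_spacing`` is the inter-axis distance of
    adjacent helices.  ``phase_offsets_deg`` fixes the azimuth origin of
    each helix: with (0, 180, 180) the zero-phase protrusion of helix 1
    points toward the tile interior (+y) and those of helices 2 and 3
    point toward -y, which encodes the side convention of the design
    blueprints.  Chromophore offsets and dipoles are in the local
    (axial, radial, tangential) frame at the placement.
    """

    rise_per_bp: float = 2.81  # Å
    bp_per_turn: float = 11.0
    helix_spacing: float = 22.0  # Å
    phase_offsets_deg: tuple[float, float, float] = (0.0, 180.0, 180.0)
    donor_offset: tuple[float, float, float] = (14.4, 12.0, -4.3)  # Å
    acceptor_offset: tuple[float, float, float] = (14.4, 12.0, -4.3)  # Å
    donor_dipole: tuple[float, float, float] = (0.0, 0.0, 1.0)
    acceptor_dipole: tuple[float, float, float] = (0.0, 0.0, 1.0)
    max_offset_bp: int = 60

    def __post_init__(self) -> None:
        if self.rise_per_bp <= 0:
            raise ValueError("rise per bp must be positive")
        if self.bp_per_turn <= 0:
            raise ValueError("bp per turn must be positive")
        if self.helix_spacing <= 0:
            raise ValueError("helix spacing must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "TileParams":
        raw = json.loads(Path(path).read_text())
        tuple_keys = {
            "phase_offsets_deg",
            "donor_offset",
            "acceptor_offset",
            "donor_dipole",
            "acceptor_dipole",
        }
        kwargs = {k: tuple(v) if k in tuple_keys else v for k, v in raw.items()}
        return cls(**kwargs)


@dataclass
class Scaffold3D:
    """Realized coarse-grained tile: helix axes and fluorophore geometry."""

    params: TileParams
    design: TileDesign
    helix_axes: dict  # helix index -> (start, end) Å, covering placements
    donor_point: np.ndarray  # chromophore centre, Å
    acceptor_point: np.ndarray
    donor_dipole: np.ndarray  # unit vector
    acceptor_dipole: np.ndarray

    @property
    def distance_angstrom(self) -> float:
        return float(np.linalg.norm(self.acceptor_point - self.donor_point))

    @property
    def distance_nm(self) -> float:
        return self.distance_angstrom / 10.0

    def dipole_pair(self) -> DipolePair:
        return DipolePair(
            donor_dipole=self.donor_dipole,
            acceptor_dipole=self.acceptor_dipole,
            separation=self.acceptor_point - self.donor_point,
        )


def parse_design(notation: str) -> TileDesign:
    """Parse an ``x,y-Bz-Pw`` design string."""
    m = _DESIGN_RE.match(notation)
    if m is None:
        # pinpoint the offending token for the error message
        if "B" not in notation.upper():
            detail = "missing B (donor) placement"
        elif "P" not in notation.upper():
            detail = "missing P (acceptor) placement"
        elif "," not in notation:
            detail = "missing comma-separated helix indices"
        else:
            detail = "does not match '<x>,<y>-B<z>P<w>'"
        raise DesignParseError(f"cannot parse design {notation!r}: {detail}")

    def _offset(tok: str) -> int:
        return int(tok.strip().strip("()").replace(" ", ""))

    return TileDesign(
        donor=Placement(int(m["hd"]), _offset(m["zd"])),
        acceptor=Placement(int(m["ha"]), _offset(m["za"])),
        label=notation.strip(),
    )


def _local_frame(placement: Placement, params: TileParams):
    """Attachment point and (axial, radial, tangential) unit vectors."""
    k = placement.offset_bp
    h = placement.helix
    attach = np.array(
        [k * params.rise_per_bp, (h - 1) * params.helix_spacing, 0.0]
    )
    theta = np.deg2rad(
        params.phase_offsets_deg[h - 1] + k * 360.0 / params.bp_per_turn
    )
    e_axial = np.array([1.0 if k >= 0 else -1.0, 0.0, 0.0])
    e_radial = np.array([0.0, np.cos(theta), np.sin(theta)])
    e_tangential = np.cross([1.0, 0.0, 0.0], e_radial)
    return attach, e_axial, e_radial, e_tangential


def _fluorophore(placement: Placement, offset, dipole, params: TileParams):
    attach, ea, er, et = _local_frame(placement, params)
    a, rho, tau = offset
    point = attach + a * ea + rho * er + tau * et
    d = dipole[0] * ea + dipole[1] * er + dipole[2] * et
    return point, d / np.linalg.norm(d)


def build_tile(design: TileDesign, params: TileParams | None = None) -> Scaffold3D:
    """Realize a design as 3D fluorophore positions and dipoles."""
    params = params or TileParams()
    for role, pl in (("donor", design.donor), ("acceptor", design.acceptor)):
        if abs(pl.offset_bp) > params.max_offset_bp:
            raise ValueError(
                f"{role} offset {pl.offset_bp} bp exceeds the helix length "
                f"bound of ±{params.max_offset_bp} bp"
            )
    donor_pt, donor_dip = _fluorophore(
        design.donor, params.donor_offset, params.donor_dipole, params
    )
    acc_pt, acc_dip = _fluorophore(
        design.acceptor, params.acceptor_offset, params.acceptor_dipole, params
    )
    span = params.max_offset_bp * params.rise_per_bp
    axes = {
        h: (
            np.array([-span, (h - 1) * params.helix_spacing, 0.0]),
            np.array([span, (h - 1) * params.helix_spacing, 0.0]),
        )
        for h in (1, 2, 3)
    }
    return Scaffold3D(
        params=params,
        design=design,
        helix_axes=axes,
        donor_point=donor_pt,
        acceptor_point=acc_pt,
        donor_dipole=donor_dip,
        acceptor_dipole=acc_dip,
    )


def predict_distance(
    design: TileDesign | str, params: TileParams | None = None
) -> float:
    """Donor-acceptor chromophore centre distance in nm."""
    if isinstance(design, str):
        design = parse_design(design)
    return build_tile(design, params).distance_nm


def predict_kappa_squared(
    design: TileDesign | str, params: TileParams | None = None
) -> float:
    """Orientation factor κ² of the model dipoles for a design."""
    if isinstance(design, str):
        design = parse_design(design)
    return kappa_squared(build_tile(design, params).dipole_pair())


def rank_designs(
    designs: Sequence[TileDesign | str],
    params: TileParams | None = None,
    r0_nm: float | None = None,
) -> list[dict]:
    """Rank designs by predicted distance, ascending; ties keep input order.

    Returns one record per design with the label, predicted distance (nm),
    model κ², and — when ``r0_nm`` is given — the predicted transfer
    efficiency at that Förster radius.
    """
    if len(designs) == 0:
        raise ValueError("need at least one design to rank")
    parsed = [parse_design(d) if isinstance(d, str) else d for d in designs]
    records = []
    for i, d in enumerate(parsed):
        dist = predict_distance(d, params)
        rec = {
            "design": d.label or f"design_{i}",
            "distance_nm": dist,
            "kappa2": predict_kappa_squared(d, params),
            "input_order": i,
        }
        if r0_nm is not None:
            rec["efficiency"] = fret_efficiency(dist, r0_nm)
        records.append(rec)
    records.sort(key=lambda r: (r["distance_nm"], r["input_order"]))
    return records


def write_pseudo_pdb(scaffold: Scaffold3D, path: str | Path, n_axis_points: int = 25) -> None:
    """Write fluorophore centres and helix-axis traces as pseudo-atoms."""
    import gemmi

    st = gemmi.Structure()
    st.name = scaffold.design.label or "tile"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")

    def _residue(name: str, seqid: int, points, elem: str):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        res.het_flag = "H"
        for j, p in enumerate(points):
            atom = gemmi.Atom()
            atom.name = f"X{j + 1}"
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*p)
            res.add_atom(atom)
        return res

    chain.add_residue(_residue("DON", 1, [scaffold.donor_point], "C"))
    chain.add_residue(_residue("ACC", 2, [scaffold.acceptor_point], "N"))
    for h, (start, end) in scaffold.helix_axes.items():
        pts = [start + t * (end - start) for t in np.linspace(0, 1, n_axis_points)]
        chain.add_residue(_residue("AXS", 2 + h, pts, "P"))
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
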