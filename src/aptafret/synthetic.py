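"""Synthetic-data generators with recorded ground truth.

Every input type the analysis modules consume can be generated here with
known truth, so each pipeline stage is testable end to end:

* Gaussian excitation/emission spectra at the aptamer-fluorophore maxima
  (donor ex 485 / em 505 nm, acceptor ex 585 / em 620 nm);
* fluorescence intensity tables built by inverting the crosstalk-
  corrected FRET formula around a chosen true statistic;
* rigid-pose coordinate ensembles — a fixed acceptor aptamer/ligand and
  a donor perturbed by Gaussian translations and small-angle Gaussian
  rotations, mimicking the near-Gaussian particle distributions seen
  along cryo-EM variability reaction coordinates;
* SHAPE gel lane profiles as Gaussian bands over a smooth exponential
  background, with reverse-transcriptase stop bands present in every
  lane including the mock.

Gaussian shapes are a deliberate simplification (real spectra and bands
are asymmetric) chosen so that closed-form oracles exist for every
generated quantity.  All generators are deterministic given a seed and
return a :class:`GroundTruth` record; the file-writing variants store it
as a JSON sidecar next to the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fluorometry import ChannelSet, CrosstalkFactors, IntensityTable
from .forster import Spectrum
from .shape import BandMap, LaneProfile

__all__ = [
    "GroundTruth",
    "gen_spectra",
    "gen_intensity_table",
    "gen_ensemble",
    "write_ensemble",
    "gen_lane_set",
]

DONOR_EX_MAX_NM = 485.0
DONOR_EM_MAX_NM = 505.0
ACCEPTOR_EX_MAX_NM = 585.0
ACCEPTOR_EM_MAX_NM = 620.0


@dataclass
class GroundTruth:
    """Machine-readable record of what a generator actually produced."""

    seed: int | None = None
    fret: float | None = None
    factors: dict | None = None
    distance: float | None = None
    transforms: list | None = None
    reactivities: dict | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        Path(path).write_text(
            json.dumps(_clean(dataclasses.asdict(self)), indent=1, sort_keys=True)
        )


def _gaussian(wl: np.ndarray, centre: float, sigma: float, amplitude: float):
    return amplitude * np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def gen_spectra(
    donor_ex_max: float = DONOR_EX_MAX_NM,
    donor_em_max: float = DONOR_EM_MAX_NM,
    acceptor_ex_max: float = ACCEPTOR_EX_MAX_NM,
    acceptor_em_max: float = ACCEPTOR_EM_MAX_NM,
    donor_sigma: float = 20.0,
    acceptor_sigma: float = 25.0,
    donor_amplitude: float = 1.0,
    acceptor_amplitude: float = 1.0e5,  # peak molar absorptivity, M^-1 cm^-1
    grid_nm: tuple[float, float] = (350.0, 750.0),
) -> dict[str, Spectrum]:
    """Gaussian spectra on a 1 nm grid for both fluorophore complexes.

    Returns ``donor_excitation``, ``donor_emission``,
    ``acceptor_excitation`` (molar-absorptivity scale) and
    ``acceptor_emission``.
    """
    if donor_sigma <= 0 or acceptor_sigma <= 0:
        raise ValueError("spectral widths must be positive")
    wl = np.arange(grid_nm[0], grid_nm[1] + 0.5, 1.0)
    return {
        "donor_excitation": Spectrum(
            wl, _gaussian(wl, donor_ex_max, donor_sigma, donor_amplitude), "absorptivity"
        ),
        "donor_emission": Spectrum(
            wl, _gaussian(wl, donor_em_max, donor_sigma, donor_amplitude), "emission"
        ),
        "acceptor_excitation": Spectrum(
            wl,
            _gaussian(wl, acceptor_ex_max, acceptor_sigma, acceptor_amplitude),
            "absorptivity",
        ),
        "acceptor_emission": Spectrum(
            wl,
            _gaussian(wl, acceptor_em_max, acceptor_sigma, acceptor_amplitude),
            "emission",
        ),
    }


def gen_intensity_table(
    true_sensitized: float = 60.0,
    true_donor_em: float = 100.0,
    donor_leak: float = 0.05,
    acceptor_direct: float = 0.02,
    i_acceptor_acceptor: float = 150.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | None = None,
    channels: ChannelSet | None = None,
) -> tuple[IntensityTable, GroundTruth]:
    """Forward-model a double-labelled intensity table plus crosstalk lanes.

    The transfer-channel reading is assembled as
    ``I_DA(ex_D, em_A) = true_sensitized + A_dir * I_AA + D_Leak * I_DD``,
    so the noise-free table fed back through the correction returns
    exactly ``true_sensitized / (true_sensitized + true_donor_em)``.
    Donor-only and acceptor-only rows consistent with the requested
    factors are included so the factors can be re-measured from the
    table.  ``noise_sd`` applies multiplicative Gaussian noise per
    reading.
    """
    if min(true_sensitized, true_donor_em, donor_leak, acceptor_direct,
           i_acceptor_acceptor) < 0:
        raise ValueError("forward-model inputs must be non-negative")
    ch = channels or ChannelSet()
    rng = np.random.default_rng(seed)
    i_da = true_sensitized + acceptor_direct * i_acceptor_acceptor + donor_leak * true_donor_em
    donor_ref = 200.0  # arbitrary donor-only brightness
    rows = []
    for rep in range(1, n_replicates + 1):
        base = [
            ("double", ch.ex_donor, ch.em_acceptor, i_da),
            ("double", ch.ex_acceptor, ch.em_acceptor, i_acceptor_acceptor),
            ("double", ch.ex_donor, ch.em_donor, true_donor_em),
            ("donor_only", ch.ex_donor, ch.em_acceptor, donor_leak * donor_ref),
            ("donor_only", ch.ex_donor, ch.em_donor, donor_ref),
            ("acceptor_only", ch.ex_donor, ch.em_acceptor,
             acceptor_direct * i_acceptor_acceptor),
            ("acceptor_only", ch.ex_acceptor, ch.em_acceptor, i_acceptor_acceptor),
        ]
        for sample, ex, em, value in base:
            if noise_sd > 0:
                value = max(0.0, value * (1.0 + noise_sd * rng.standard_normal()))
            rows.append((sample, ex, em, value, rep))
    denom = true_sensitized + true_donor_em
    truth = GroundTruth(
        seed=seed,
        fret=true_sensitized / denom if denom > 0 else 0.0,
        factors={"donor_leak": donor_leak, "acceptor_direct": acceptor_direct},
        extra={"noise_sd": noise_sd, "n_replicates": n_replicates},
    )
    return IntensityTable.from_records(rows), truth


# --- rigid-pose ensembles ---------------------------------------------------

def _chromophore_cloud(rng_shape: str = "donor") -> np.ndarray:
    """A rigid ~20-atom planar point cloud shaped like a chromophore.

    Two fused rings plus an exocyclic tail in the xy plane; anisotropic
    by construction so the principal-axis dipole proxy is
    well-conditioned.
    """
    ring1 = [
        (2.0 * np.cos(a), 2.0 * np.sin(a), 0.0)
        for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)
    ]
    ring2 = [
        (5.0 + 1.6 * np.cos(a), 1.6 * np.sin(a), 0.0)
        for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)
    ]
    tail = [(7.5 + 1.1 * i, 0.4 * (-1) ** i, 0.0) for i in range(6)]
    cloud = np.array(ring1 + ring2 + tail)
    if rng_shape == "acceptor":
        cloud = cloud * 1.08  # slightly larger, distinct species
    return cloud - cloud.mean(axis=0)


def _stem_atoms(origin: np.ndarray) -> np.ndarray:
    """A short dummy aptamer stem (5 points) next to a ligand."""
    return origin + np.array(
        [[0.0, 6.0, 1.5 * i] for i in range(5)], dtype=float
    )


def _random_rotation(sigma_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Small-angle random rotation: axis uniform, angle ~ |N(0, sigma)|."""
    if sigma_deg == 0:
        return np.eye(3)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(abs(rng.normal(0.0, sigma_deg)))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def gen_ensemble(
    n_members: int = 10,
    base_distance: float = 32.0,  # Å between chromophore centres
    translational_sd: float = 1.0,  # Å, isotropic
    rotational_sd_deg: float = 0.0,
    seed: int | None = None,
) -> tuple[dict, GroundTruth]:
    """Rigid-pose ensemble coordinates with recorded true transforms.

    The acceptor aptamer/ligand is fixed; each member's donor is the base
    donor perturbed by a random rigid transform about its chromophore
    centre (Gaussian translation, small-angle Gaussian rotation).
    Returns ``{"members": [...], "donor_base": ..., "acceptor": ...}``
    where each member is a dict of donor ligand/stem coordinates, plus
    the ground truth (true transforms, true base distance).
    """
    if n_members < 1:
        raise ValueError("need at least one member")
    if translational_sd < 0 or rotational_sd_deg < 0:
        raise ValueError("spread parameters must be non-negative")
    rng = np.random.default_rng(seed)
    acceptor_ligand = _chromophore_cloud("acceptor")
    donor_ligand = _chromophore_cloud("donor") + np.array([base_distance, 0.0, 0.0])
    members = []
    transforms = []
    for _ in range(n_members):
        rot = _random_rotation(rotational_sd_deg, rng)
        shift = (
            rng.normal(0.0, translational_sd, size=3)
            if translational_sd > 0
            else np.zeros(3)
        )
        centre = donor_ligand.mean(axis=0)
        lig = (donor_ligand - centre) @ rot.T + centre + shift
        members.append(
            {
                "donor_ligand": lig,
                "donor_stem": _stem_atoms(lig.mean(axis=0)),
                "acceptor_ligand": acceptor_ligand.copy(),
                "acceptor_stem": _stem_atoms(acceptor_ligand.mean(axis=0)),
            }
        )
        transforms.append({"rotation": rot, "translation": shift})
    truth = GroundTruth(
        seed=seed,
        distance=base_distance,
        transforms=transforms,
        extra={
            "translational_sd": translational_sd,
            "rotational_sd_deg": rotational_sd_deg,
        },
    )
    return {
        "members": members,
        "donor_base": donor_ligand,
        "acceptor": acceptor_ligand,
    }, truth


def write_ensemble(
    out_dir: str | Path,
    donor_resname: str = "DFB",
    acceptor_resname: str = "HBC",
    **kwargs,
) -> tuple[list[Path], GroundTruth]:
    """Generate an ensemble and write one PDB per member plus a truth JSON.

    Donor ligand atoms are named C1..Cn in residue ``donor_resname``
    (chain A, after a dummy stem residue), acceptor likewise in chain B,
    matching what :func:`aptafret.ensemble.read_members` expects.
    """
    import gemmi

    ensemble, truth = gen_ensemble(**kwargs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _residue(name: str, seqid: int, coords: np.ndarray, elem: str) -> gemmi.Residue:
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        res.het_flag = "H"
        for j, p in enumerate(coords):
            atom = gemmi.Atom()
            # zero-padded names keep (residue, atom) sort order positional
            atom.name = f"{elem}{j + 1:02d}"
            atom.element = gemmi.Element(elem)
            atom.occ = 1.0
            atom.pos = gemmi.Position(*p)
            res.add_atom(atom)
        return res

    paths = []
    for i, member in enumerate(ensemble["members"]):
        st = gemmi.Structure()
        st.name = f"member_{i:03d}"
        model = gemmi.Model("1")
        chain_a = gemmi.Chain("A")
        chain_a.add_residue(_residue("STM", 1, member["donor_stem"], "P"))
        chain_a.add_residue(_residue(donor_resname, 2, member["donor_ligand"], "C"))
        chain_b = gemmi.Chain("B")
        chain_b.add_residue(_residue("STM", 1, member["acceptor_stem"], "P"))
        chain_b.add_residue(_residue(acceptor_resname, 2, member["acceptor_ligand"], "C"))
        model.add_chain(chain_a)
        model.add_chain(chain_b)
        st.add_model(model)
        st.setup_entities()
        path = out_dir / f"member_{i:03d}.pdb"
        st.write_pdb(str(path))
        paths.append(path)
    truth.to_json(out_dir / "ground_truth.json")
    return paths, truth


# --- SHAPE gel lanes --------------------------------------------------------

def gen_lane_set(
    reactivities: dict[str, dict[str, float]],
    band_map: BandMap,
    band_sigma: float = 2.5,  # px
    reference_amplitude: float = 100.0,
    baseline_amplitude: float = 5.0,
    baseline_scale: float = 300.0,  # px decay length of the smooth background
    stop_positions: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.0,
    n_points: int = 600,
    seed: int | None = None,
) -> tuple[dict[str, LaneProfile], GroundTruth]:
    """Synthetic gel lanes: Gaussian bands over a smooth background.

    ``reactivities[condition][nucleotide]`` are ground-truth reactivities
    relative to the reference (whose amplitude is fixed at
    ``reference_amplitude`` in every lane, including the mock, emulating
    a ubiquitous termination product).  ``stop_positions`` maps
    nucleotide id -> per-condition amplitude for RT-stop artifact bands
    added to every listed lane; the mock lane receives bands only from
    ``stop_positions`` plus the reference.  Additive Gaussian noise of
    absolute scale ``noise_sd`` is applied when positive.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(n_points, dtype=float)
    baseline = baseline_amplitude * np.exp(-x / baseline_scale)
    conditions = ["mock"] + [c for c in reactivities if c != "mock"]
    stop_positions = stop_positions or {}
    lanes = {}
    for cond in conditions:
        profile = baseline.copy()
        # reference band in every lane fixes the normalization scale
        profile += _gaussian(
            x, band_map.position_of(band_map.reference), band_sigma, reference_amplitude
        )
        if cond != "mock":
            for nt, r in reactivities[cond].items():
                if nt == band_map.reference:
                    continue
                profile += _gaussian(
                    x, band_map.position_of(nt), band_sigma, reference_amplitude * r
                )
        for nt, per_cond in stop_positions.items():
            amp = per_cond.get(cond, 0.0)
            if amp > 0:
                profile += _gaussian(
                    x, band_map.position_of(nt), band_sigma, reference_amplitude * amp
                )
        if noise_sd > 0:
            profile = np.maximum(0.0, profile + rng.normal(0.0, noise_sd, n_points))
        lanes[cond] = LaneProfile(position=x, intensity=profile, condition=cond)
    truth = GroundTruth(
        seed=seed,
        reactivities=reactivities,
        extra={
            "stop_positions": stop_positions,
            "band_sigma": band_sigma,
            "noise_sd": noise_sd,
            "reference": band_map.reference,
        },
    )
    return lanes, truth
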