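"""SHAPE gel densitometry: band quantification and reactivity calls.

A SHAPE experiment probes per-nucleotide backbone flexibility: flexible
nucleotides are acylated, reverse transcription stops at the adducts,
and the cDNA pool is resolved on a sequencing gel.  Each lane is one
condition (mock = no reagent, apo = reagent without ligand, plus
ligand-bound lanes); band intensity at a nucleotide's migration position
is proportional to its reactivity.

The quantification follows gel densitometry practice: a 1-D lane profile
(from a TSV trace or summed from an image region), per-band local linear
baseline subtraction, peak-height readout within a window around each
mapped band position, and normalization of every lane to a designated
reference nucleotide (default ``C28``, a tetraloop position assumed
invariant to ligand binding, so the reference reactivity is 1 in every
lane by construction).  Nucleotides whose mock-lane signal is high are
flagged as reverse-transcriptase stop artifacts and excluded from
protected/enhanced calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingDataError

__all__ = [
    "LaneProfile",
    "BandMap",
    "ReactivityTable",
    "extract_profile",
    "quantify_bands",
    "normalize_reactivity",
    "differential_reactivity",
    "flag_rt_stops",
    "quantify_lanes",
]

#: conditions used in the probing series
KNOWN_CONDITIONS = ("mock", "apo", "HBC485", "HBC497", "HBC620")

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_STOP_THRESHOLD = 0.3
#: floor used for ratios with (near-)zero denominators
DEFAULT_RATIO_FLOOR = 1e-3


@dataclass
class LaneProfile:
    """1-D densitometry trace of one gel lane."""

    position: np.ndarray  # pixel index, monotone increasing
    intensity: np.ndarray  # arbitrary units >= 0
    condition: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        self.position, self.intensity = pos, inten
        if pos.size < 32:
            raise ValueError("lane profile needs at least 32 samples")
        if pos.size != inten.size:
            raise ValueError("position and intensity differ in length")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str = "") -> "LaneProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            position=df["position"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
            condition=condition or Path(path).stem,
        )

    def scaled(self, factor: float) -> "LaneProfile":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return LaneProfile(self.position, self.intensity * factor, self.condition)


@dataclass
class BandMap:
    """Nucleotide id -> expected migration position (px), plus reference.

    Positions must be strictly monotone in nucleotide order (the order of
    ``nucleotides``); the sequencing-ladder calibration that produces
    them is done upstream.
    """

    nucleotides: list[str]
    positions: np.ndarray
    reference: str = "C28"
    unquantifiable: frozenset = frozenset()  # e.g. gel-compression region

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        self.positions = pos
        if len(self.nucleotides) != pos.size:
            raise ValueError("nucleotide list and positions differ in length")
        diffs = np.diff(pos)
        if pos.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("band positions must be strictly monotone")
        if self.reference not in self.nucleotides:
            raise MissingDataError(f"reference {self.reference!r} not in band map")

    @classmethod
    def from_tsv(cls, path: str | Path, reference: str = "C28") -> "BandMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            nucleotides=df["nucleotide_id"].astype(str).tolist(),
            positions=df["position"].to_numpy(),
            reference=reference,
        )

    def position_of(self, nucleotide: str) -> float:
        return float(self.positions[self.nucleotides.index(nucleotide)])


@dataclass
class ReactivityTable:
    """Per-condition normalized reactivities plus artifact/classification calls."""

    raw: pd.DataFrame  # index nucleotide, columns condition
    normalized: pd.DataFrame
    rt_stops: list[str] = field(default_factory=list)
    classifications: dict = field(default_factory=dict)  # condition -> {nt: call}

    def to_tsv(self, path: str | Path) -> None:
        out = self.normalized.copy()
        out.columns = [f"R_{c}" for c in out.columns]
        out["rt_stop"] = [nt in self.rt_stops for nt in out.index]
        for cond, calls in self.classifications.items():
            out[f"call_{cond}"] = [calls.get(nt, "") for nt in out.index]
        out.to_csv(path, sep="\t", index_label="nucleotide_id")


def extract_profile(
    roi: np.ndarray, lane_axis: int = 0, condition: str = ""
) -> LaneProfile:
    """Collapse a rectangular grayscale ROI to a 1-D lane profile.

    Pixels are summed across the lane width; ``lane_axis`` is the
    migration axis of the ROI array.
    """
    arr = np.asarray(roi, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("ROI must be a non-empty 2-D array")
    width_axis = 1 - lane_axis
    if arr.shape[width_axis] < 3:
        raise ValueError("ROI must be at least 3 px wide across the lane")
    profile = arr.sum(axis=width_axis)
    return LaneProfile(
        position=np.arange(profile.size, dtype=float),
        intensity=profile,
        condition=condition,
    )


def quantify_bands(
    profile: LaneProfile, band_map: BandMap, window: int = 5
) -> pd.Series:
    """Baseline-subtracted peak height per mapped band.

    For each nucleotide, a local linear baseline is drawn between the
    profile values at the edges of ``position ± window`` and subtracted;
    the reported intensity is the maximum of the residual inside the
    window, floored at 0.  Peak height (not area) is the readout, the
    standard manual-densitometry convention; see
    :func:`quantify_bands_area` for the integral alternative.
    """
    return _quantify(profile, band_map, window, mode="height")


def quantify_bands_area(
    profile: LaneProfile, band_map: BandMap, window: int = 5
) -> pd.Series:
    """Baseline-subtracted integrated band area (trapezoid over the window)."""
    return _quantify(profile, band_map, window, mode="area")


def _quantify(
    profile: LaneProfile, band_map: BandMap, window: int, mode: str
) -> pd.Series:
    if window < 1:
        raise ValueError("window must be >= 1 px")
    pos, inten = profile.position, profile.intensity
    lo, hi = pos[0], pos[-1]
    quantified = {}
    intervals = []
    for nt, centre in zip(band_map.nucleotides, band_map.positions):
        if nt in band_map.unquantifiable:
            quantified[nt] = np.nan
            continue
        if not (lo <= centre <= hi):
            raise ValueError(
                f"band {nt} at position {centre:g} lies outside the profile "
                f"[{lo:g}, {hi:g}]"
            )
        left = max(lo, centre - window)
        right = min(hi, centre + window)
        intervals.append((nt, left, right))
        mask = (pos >= left) & (pos <= right)
        x, y = pos[mask], inten[mask]
        y_l = float(np.interp(left, pos, inten))
        y_r = float(np.interp(right, pos, inten))
        baseline = y_l + (x - left) * ((y_r - y_l) / (right - left) if right > left else 0.0)
        residual = y - baseline
        if mode == "height":
            value = float(residual.max())
        else:
            value = float(np.trapezoid(np.maximum(residual, 0.0), x))
        if value < 0:
            warnings.warn(f"band {nt}: negative baseline-subtracted peak, floored to 0")
            value = 0.0
        quantified[nt] = value
    overlaps = [
        (a[0], b[0])
        for a, b in zip(intervals, intervals[1:])
        if min(a[2], b[2]) > max(a[1], b[1])
    ]
    if overlaps:
        warnings.warn(f"overlapping band windows: {overlaps}")
    return pd.Series(quantified, name=profile.condition or "intensity")


def normalize_reactivity(raw: pd.Series, reference: str = "C28") -> pd.Series:
    """Normalize band intensities to the reference nucleotide (R_ref = 1)."""
    if reference not in raw.index:
        raise MissingDataError(f"reference {reference!r} absent from intensities")
    ref_val = raw[reference]
    if not ref_val > 0:
        raise DegenerateInputError(
            f"reference {reference!r} intensity is {ref_val:g}; cannot normalize"
        )
    return raw / ref_val


def differential_reactivity(
    r_apo: pd.Series,
    r_bound: pd.Series,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
    exclude: set | frozenset = frozenset(),
) -> dict:
    """Classify nucleotides as protected / enhanced / unchanged.

    Protected: apo reactivity exceeds bound by >= fold_threshold (the
    nucleotide rigidifies on ligand binding).  Enhanced: bound exceeds
    apo by >= fold_threshold (e.g. a base displaced out of a stack by the
    incoming ligand).  Reactivities below ``ratio_floor`` are floored
    before forming ratios.  ``exclude`` positions (RT stops,
    unquantifiable bands) are skipped.
    """
    if fold_threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    shared = [nt for nt in r_apo.index if nt in r_bound.index and nt not in exclude]
    if not shared:
        raise MissingDataError("apo and bound reactivity tables share no nucleotides")
    calls = {}
    for nt in shared:
        a = max(float(r_apo[nt]), ratio_floor)
        b = max(float(r_bound[nt]), ratio_floor)
        if np.isnan(r_apo[nt]) or np.isnan(r_bound[nt]):
            continue
        if a / b >= fold_threshold:
            calls[nt] = "protected"
        elif b / a >= fold_threshold:
            calls[nt] = "enhanced"
        else:
            calls[nt] = "unchanged"
    return calls


def flag_rt_stops(
    mock_normalized: pd.Series,
    stop_threshold: float = DEFAULT_STOP_THRESHOLD,
    reference: str | None = None,
) -> list[str]:
    """Nucleotides with strong mock-lane signal: RT termination artifacts.

    The mock lane saw no SHAPE reagent, so any band there reflects
    premature reverse-transcriptase termination (typically at stable
    structure 3' ends), not chemical reactivity.  Positions at or above
    ``stop_threshold`` (relative to the reference band) are flagged.
    The reference itself is never flagged — it defines the scale.
    """
    return [
        str(nt)
        for nt, v in mock_normalized.items()
        if np.isfinite(v) and v >= stop_threshold and nt != reference
    ]


def quantify_lanes(
    profiles: dict[str, LaneProfile],
    band_map: BandMap,
    window: int = 5,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    stop_threshold: float = DEFAULT_STOP_THRESHOLD,
    apo_condition: str = "apo",
    mock_condition: str = "mock",
) -> ReactivityTable:
    """Full pipeline: quantify, normalize, flag RT stops, classify.

    ``profiles`` maps condition name -> lane profile and must contain the
    apo lane; the mock lane is optional (without it no RT-stop flags are
    made).  Every ligand-bound condition is classified against apo,
    excluding flagged and unquantifiable positions.
    """
    if apo_condition not in profiles:
        raise MissingDataError(f"apo lane {apo_condition!r} is required")
    raw = pd.DataFrame(
        {cond: quantify_bands(p, band_map, window) for cond, p in profiles.items()}
    )
    normalized = raw.apply(lambda col: normalize_reactivity(col, band_map.reference))
    rt_stops: list[str] = []
    if mock_condition in profiles:
        rt_stops = flag_rt_stops(
            normalized[mock_condition], stop_threshold, reference=band_map.reference
        )
    exclude = set(rt_stops) | set(band_map.unquantifiable) | {band_map.reference}
    classifications = {
        cond: differential_reactivity(
            normalized[apo_condition],
            normalized[cond],
            fold_threshold,
            exclude=exclude,
        )
        for cond in profiles
        if cond not in (apo_condition, mock_condition)
    }
    return ReactivityTable(
        raw=raw,
        normalized=normalized,
        rt_stops=rt_stops,
        classifications=classifications,
    )
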