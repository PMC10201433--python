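"""Crosstalk-corrected FRET output from fluorescence intensity tables.

The ratiometric statistic computed here quantifies sensitized acceptor
emission from a double-labelled sample after removing the two spectral
crosstalk contributions that contaminate the transfer channel
(donor excitation / acceptor emission):

* donor leak ``D_Leak`` — the fraction of donor emission that bleeds into
  the acceptor emission channel, measured on a donor-only sample;
* acceptor direct excitation ``A_dir`` — the fraction of acceptor signal
  produced by directly exciting the acceptor at the donor excitation
  wavelength, measured on an acceptor-only sample.

With ``N = I_DA(ex_D, em_A) - A_dir * I_DA(ex_A, em_A)
- D_Leak * I_DA(ex_D, em_D)`` the FRET output is ``N / (N + I_DA(ex_D,
em_D))``.  The statistic is a corrected proximity ratio, not a
photophysically calibrated transfer efficiency: no gamma factor is
applied.  Values are reported unclamped so that noise-driven negative
numerators remain visible in replicate statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingDataError

__all__ = [
    "ChannelSet",
    "CrosstalkFactors",
    "IntensityTable",
    "FretResult",
    "donor_leak",
    "acceptor_direct",
    "fret_output",
    "fret_replicates",
    "read_intensity_table",
]

SAMPLE_KINDS = ("donor_only", "acceptor_only", "double")

#: wavelength match tolerance when looking up channel readings, nm
_WL_ATOL = 0.5


@dataclass(frozen=True)
class ChannelSet:
    """Excitation/emission wavelengths (nm) of the four-channel scheme.

    Defaults are the Broccoli/DFHBI-1T donor (ex 460, em 505) and
    Pepper/HBC620 acceptor (ex 585, em 620) channels.
    """

    ex_donor: float = 460.0
    em_donor: float = 505.0
    ex_acceptor: float = 585.0
    em_acceptor: float = 620.0

    def __post_init__(self) -> None:
        for name in ("ex_donor", "em_donor", "ex_acceptor", "em_acceptor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.em_donor > self.ex_donor:
            raise ValueError("donor emission must be red of donor excitation")
        if not self.em_acceptor > self.ex_acceptor:
            raise ValueError("acceptor emission must be red of acceptor excitation")

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSet":
        return cls(
            ex_donor=float(d["ex_donor"]),
            em_donor=float(d["em_donor"]),
            ex_acceptor=float(d["ex_acceptor"]),
            em_acceptor=float(d["em_acceptor"]),
        )


@dataclass(frozen=True)
class CrosstalkFactors:
    """Donor-leak and acceptor-direct-excitation correction ratios."""

    donor_leak: float
    acceptor_direct: float

    def __post_init__(self) -> None:
        for name in ("donor_leak", "acceptor_direct"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


class IntensityTable:
    """Long-format fluorescence readings.

    Wraps a DataFrame with columns ``sample`` (one of ``donor_only``,
    ``acceptor_only``, ``double``), ``ex_nm``, ``em_nm``, ``intensity``
    and ``replicate``.  The (sample, ex, em, replicate) key must be
    unique and intensities non-negative.
    """

    COLUMNS = ("sample", "ex_nm", "em_nm", "intensity", "replicate")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"intensity table lacks columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        bad = set(df["sample"]) - set(SAMPLE_KINDS)
        if bad:
            raise ValueError(f"unknown sample kinds: {sorted(bad)}")
        if (df["intensity"] < 0).any():
            raise ValueError("negative intensities are not allowed")
        if df.duplicated(subset=["sample", "ex_nm", "em_nm", "replicate"]).any():
            raise ValueError("duplicate (sample, ex, em, replicate) keys")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntensityTable":
        """Build from (sample, ex_nm, em_nm, intensity[, replicate]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 4:
                rec = rec + (1,)
            rows.append(dict(zip(cls.COLUMNS, rec)))
        return cls(pd.DataFrame(rows))

    def replicates(self, sample: str | None = None) -> list:
        df = self.df if sample is None else self.df[self.df["sample"] == sample]
        return sorted(df["replicate"].unique().tolist())

    def intensity(
        self,
        sample: str,
        ex_nm: float,
        em_nm: float,
        replicate: int | None = None,
    ) -> float:
        """Reading for one channel; mean across replicates if unspecified."""
        df = self.df
        m = (
            (df["sample"] == sample)
            & (np.abs(df["ex_nm"] - ex_nm) <= _WL_ATOL)
            & (np.abs(df["em_nm"] - em_nm) <= _WL_ATOL)
        )
        if replicate is not None:
            m &= df["replicate"] == replicate
        sel = df.loc[m, "intensity"]
        if sel.empty:
            rep = "" if replicate is None else f", replicate {replicate}"
            raise MissingDataError(
                f"no {sample} reading at ex {ex_nm:g} / em {em_nm:g} nm{rep}"
            )
        return float(sel.mean())

    def scaled(self, factor: float) -> "IntensityTable":
        """A copy with every intensity multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        df = self.df.copy()
        df["intensity"] = df["intensity"] * factor
        return IntensityTable(df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class FretResult:
    """FRET output with replicate statistics.

    ``fret`` is the dimensionless fraction (mean across replicates);
    ``fret_percent`` the same scaled by 100.  ``negative_flag`` is set
    when any replicate's corrected numerator was negative.
    """

    fret: float
    per_replicate: list[float] = field(default_factory=list)
    sd: float = 0.0
    negative_flag: bool = False

    @property
    def fret_percent(self) -> float:
        return 100.0 * self.fret

    @property
    def sd_percent(self) -> float:
        return 100.0 * self.sd


def donor_leak(donor_table: IntensityTable, channels: ChannelSet | None = None) -> float:
    """Donor-leak ratio from a donor-only sample.

    ``D_Leak = I_D(ex_D, em_A) / I_D(ex_D, em_D)``.
    """
    ch = channels or ChannelSet()
    leak = donor_table.intensity("donor_only", ch.ex_donor, ch.em_acceptor)
    direct = donor_table.intensity("donor_only", ch.ex_donor, ch.em_donor)
    if direct <= 0:
        raise DegenerateInputError(
            "donor-only emission at the donor channel is zero; cannot form D_Leak"
        )
    return leak / direct


def acceptor_direct(
    acceptor_table: IntensityTable, channels: ChannelSet | None = None
) -> float:
    """Acceptor direct-excitation ratio from an acceptor-only sample.

    ``A_dir = I_A(ex_D, em_A) / I_A(ex_A, em_A)``.
    """
    ch = channels or ChannelSet()
    cross = acceptor_table.intensity("acceptor_only", ch.ex_donor, ch.em_acceptor)
    direct = acceptor_table.intensity("acceptor_only", ch.ex_acceptor, ch.em_acceptor)
    if direct <= 0:
        raise DegenerateInputError(
            "acceptor-only emission at the acceptor channel is zero; cannot form A_dir"
        )
    return cross / direct


def factors_from_table(
    table: IntensityTable, channels: ChannelSet | None = None
) -> CrosstalkFactors:
    """Measure both correction factors from single-labelled rows of a table."""
    return CrosstalkFactors(
        donor_leak=donor_leak(table, channels),
        acceptor_direct=acceptor_direct(table, channels),
    )


def _fret_single(
    i_da: float, i_aa: float, i_dd: float, factors: CrosstalkFactors
) -> tuple[float, bool]:
    n = i_da - factors.acceptor_direct * i_aa - factors.donor_leak * i_dd
    denom = n + i_dd
    if denom <= 0:
        raise DegenerateInputError(
            f"FRET denominator is {denom:g} (must be positive); "
            "corrected signal plus donor emission vanished"
        )
    return n / denom, n < 0


def fret_output(
    double_table: IntensityTable,
    factors: CrosstalkFactors,
    channels: ChannelSet | None = None,
    replicate: int | None = None,
) -> FretResult:
    """Crosstalk-corrected FRET output for one double-labelled sample.

    When ``replicate`` is None the three channel readings are replicate
    means; use :func:`fret_replicates` for per-replicate statistics.
    """
    ch = channels or ChannelSet()
    i_da = double_table.intensity("double", ch.ex_donor, ch.em_acceptor, replicate)
    i_aa = double_table.intensity("double", ch.ex_acceptor, ch.em_acceptor, replicate)
    i_dd = double_table.intensity("double", ch.ex_donor, ch.em_donor, replicate)
    value, neg = _fret_single(i_da, i_aa, i_dd, factors)
    return FretResult(fret=value, per_replicate=[value], sd=0.0, negative_flag=neg)


def fret_replicates(
    tables: Sequence[IntensityTable] | IntensityTable,
    factors: CrosstalkFactors,
    channels: ChannelSet | None = None,
) -> FretResult:
    """Per-replicate FRET outputs with mean and sample SD (n-1 denominator).

    Accepts either a list of one-replicate tables or a single table whose
    ``replicate`` column distinguishes the technical replicates.
    """
    if isinstance(tables, IntensityTable):
        reps = tables.replicates("double")
        if not reps:
            raise MissingDataError("no double-labelled readings in table")
        per_tables = [(tables, r) for r in reps]
    else:
        if len(tables) == 0:
            raise MissingDataError("empty replicate list")
        per_tables = [(t, None) for t in tables]

    values: list[float] = []
    neg = False
    for table, rep in per_tables:
        res = fret_output(table, factors, channels, replicate=rep)
        values.append(res.fret)
        neg = neg or res.negative_flag
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return FretResult(fret=mean, per_replicate=values, sd=sd, negative_flag=neg)


def read_intensity_table(path: str | Path) -> IntensityTable:
    """Read a long-format TSV/CSV intensity table (delimiter sniffed)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return IntensityTable(pd.read_csv(path, sep=sep))
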