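"""Recombination-map transforms and windowed genomic tracks.

Converts between the four currencies of recombination along a partially
sex-linked chromosome:

* genetic map distance ``x`` (Morgans, from a pedigree linkage map),
* recombination fraction ``r`` per meiosis (Kosambi map function),
* population-scaled recombination rate ``rho = 4*Ne*r`` (from LD-based
  estimators, stored as a per-Kb windowed track), and
* effective population size ``Ne = rho / (4 r)``.

The physical reach of sex linkage into the pseudoautosomal region (PAR) is
quantified by :func:`linked_extent`: the distance from the PAR boundary
within which the cumulative ``rho`` stays below a threshold (conventionally
``rho = 1``), i.e. the stretch still in appreciable LD with the fully
sex-linked region (SLR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicTrack",
    "GeneticMapTable",
    "kosambi",
    "inverse_kosambi",
    "ne_from_rho_r",
    "cumulative_rho",
    "linked_extent",
    "rf_at",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenomicTrack:
    """A windowed (chrom, start, end, value) series, 0-based half-open.

    Used for rho-per-Kb tracks, windowed diversity statistics, coverage
    ratios and any other per-window scalar.  Windows must be sorted and
    non-overlapping within a chromosome; gaps between windows are allowed.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("chrom", "start", "end", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"track missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            raise ValueError("track has windows with end <= start")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_arrays(cls, chrom, start, end, value) -> "GenomicTrack":
        n = len(start)
        chrom = [chrom] * n if isinstance(chrom, str) else list(chrom)
        return cls(pd.DataFrame({
            "chrom": chrom,
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "value": np.asarray(value, dtype=float),
        }))

    @classmethod
    def read_tsv(cls, path) -> "GenomicTrack":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df[list(cls.REQUIRED)])

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    @property
    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) / 2.0

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GeneticMapTable:
    """Sex-specific genetic map: marker bp position with female/male cM.

    ``cm_avg`` (the sex-averaged map) is the arithmetic mean of the two
    sex-specific positions, matching the convention of pedigree map reports.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("chrom", "pos", "cm_female", "cm_male")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"genetic map missing columns: {missing}")
        df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        for ch, sub in df.groupby("chrom"):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"marker positions not strictly increasing on {ch}")
        if (df[["cm_female", "cm_male"]].to_numpy() < 0).any():
            raise ValueError("negative cM in genetic map")
        df = df.copy()
        df["cm_avg"] = (df["cm_female"] + df["cm_male"]) / 2.0
        self.df = df

    @classmethod
    def read_tsv(cls, path) -> "GeneticMapTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.df[list(self.REQUIRED)].to_csv(fh, sep="\t", index=False)

    def cm_at(self, chrom: str, position_bp: float, sex: str = "female") -> float:
        """Linearly interpolated cM position of ``position_bp``.

        No extrapolation: positions outside the terminal markers raise.
        """
        col = {"female": "cm_female", "male": "cm_male", "avg": "cm_avg"}[sex]
        sub = self.df[self.df["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no markers on {chrom}")
        pos = sub["pos"].to_numpy(dtype=float)
        if position_bp < pos[0] or position_bp > pos[-1]:
            raise ValueError(
                f"position {position_bp} outside map span [{pos[0]}, {pos[-1]}] on {chrom}"
            )
        return float(np.interp(position_bp, pos, sub[col].to_numpy(dtype=float)))


# ---------------------------------------------------------------------------
# map-function arithmetic
# ---------------------------------------------------------------------------

def kosambi(x):
    """Kosambi map function: map distance (Morgans) -> recombination fraction.

    r = (1/2) * (e^{4x} - 1) / (e^{4x} + 1) = (1/2) * tanh(2x).

    Unlike Haldane's function, Kosambi's allows for positive crossover
    interference at short distances; r is strictly increasing in x and
    asymptotes to 1/2.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * x)
    return float(r) if r.ndim == 0 else r


def inverse_kosambi(r):
    """Recombination fraction -> Kosambi map distance (Morgans)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    x = 0.5 * np.arctanh(2.0 * r)
    return float(x) if x.ndim == 0 else x


def ne_from_rho_r(rho: float, r: float) -> float:
    """Effective population size from Ne = rho / (4 r).

    ``rho`` and ``r`` must refer to the same interval (typically a PAR site
    versus the PAR boundary: cumulative rho over the interval paired with
    the Kosambi recombination fraction over the same interval).
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if r <= 0:
        raise ValueError("Ne = rho/(4r) is undefined at r = 0")
    return rho / (4.0 * r)


# ---------------------------------------------------------------------------
# track integration
# ---------------------------------------------------------------------------

def cumulative_rho(track: GenomicTrack, from_bp: float, to_bp: float,
                   chrom: str | None = None, on_gap: str = "zero") -> float:
    """Integrate a per-Kb rho track over [from_bp, to_bp).

    The track value is a rate per Kb, constant within each window; the
    integral is the sum of (rate * overlapped length in Kb).  Positions not
    covered by any window (e.g. an assembly gap) contribute zero by default
    (``on_gap="zero"``, logged) or raise (``on_gap="error"``).
    """
    if to_bp < from_bp:
        raise ValueError("inverted interval")
    df = track.on(chrom) if chrom is not None else track.df
    start = df["start"].to_numpy(dtype=float)
    end = df["end"].to_numpy(dtype=float)
    val = df["value"].to_numpy(dtype=float)
    lo = np.maximum(start, from_bp)
    hi = np.minimum(end, to_bp)
    ov = np.maximum(hi - lo, 0.0)
    covered = float(ov.sum())
    wanted = to_bp - from_bp
    if covered < wanted - 1e-9:
        if on_gap == "error":
            raise ValueError(
                f"interval [{from_bp}, {to_bp}) not fully covered by the track "
                f"({wanted - covered:.0f} bp uncovered)"
            )
        logger.warning(
            "cumulative_rho: %.0f bp of [%s, %s) uncovered by the track; treated as rho=0",
            wanted - covered, from_bp, to_bp,
        )
    return float(np.sum(val * ov / 1000.0))


def linked_extent(track: GenomicTrack, boundary_bp: float, rho_star: float = 1.0,
                  chrom: str | None = None) -> float:
    """Distance (bp) upstream of the PAR boundary at which cumulative rho
    reaches ``rho_star``.

    The smallest d with cumulative_rho(boundary-d, boundary) >= rho_star,
    found by walking windows away from the boundary and inverting the
    piecewise-constant rate inside the window where the threshold is
    crossed.  This measures how much PAR sequence is "tightly linked" to
    the SLR: for the conventional rho_star=1, sequence beyond d recombines
    often enough, on the coalescent timescale, to segregate independently.
    """
    if rho_star < 0:
        raise ValueError("rho_star must be non-negative")
    if rho_star == 0:
        return 0.0
    df = track.on(chrom) if chrom is not None else track.df
    df = df[df["start"] < boundary_bp].sort_values("start", ascending=False)
    acc = 0.0
    for _, w in df.iterrows():
        hi = min(float(w["end"]), boundary_bp)
        lo = float(w["start"])
        rate_per_bp = float(w["value"]) / 1000.0
        contrib = rate_per_bp * (hi - lo)
        if acc + contrib >= rho_star:
            inside = (rho_star - acc) / rate_per_bp  # rate>0 or contrib==0<need
            return (boundary_bp - hi) + inside
        acc += contrib
    raise ValueError(
        f"track accumulates only rho={acc:.4g} before the boundary; cannot reach {rho_star}"
    )


def rf_at(genetic_map: GeneticMapTable, position_bp: float, boundary_bp: float,
          chrom: str | None = None, sex: str = "female") -> float:
    """Recombination fraction between a position and the PAR boundary.

    Map distance x = |cM(position) - cM(boundary)| / 100 Morgans, with cM
    linearly interpolated between flanking markers, then r = kosambi(x).
    """
    if chrom is None:
        chroms = genetic_map.df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("chrom must be given for a multi-chromosome map")
        chrom = chroms[0]
    cm_pos = genetic_map.cm_at(chrom, position_bp, sex=sex)
    cm_bnd = genetic_map.cm_at(chrom, boundary_bp, sex=sex)
    x = abs(cm_pos - cm_bnd) / 100.0
    return kosambi(x)
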