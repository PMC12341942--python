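"""Genetic maps: genome coordinates in centiMorgans with physical anchors.

A :class:`GeneticMap` holds, per chromosome, a set of (bp, cM) anchor points.
Genetic positions between anchors are linearly interpolated; positions outside
the anchored range clamp to the map ends. Genetic lengths are carried in cM
internally and converted to Morgans only inside the admixture-time estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeMap",
    "GeneticMap",
    "make_uniform_map",
    "write_plink_map",
    "read_plink_map",
]


@dataclass(frozen=True)
class ChromosomeMap:
    """Map anchors for one chromosome.

    Parameters
    ----------
    name : chromosome identifier (e.g. ``"1"``).
    bp : 1-based physical positions, strictly increasing.
    cm : genetic positions in cM, nondecreasing, same length as ``bp``.
    """

    name: str
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise ValueError(f"chromosome {self.name}: need >=2 (bp, cM) anchors")
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"chromosome {self.name}: bp not strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"chromosome {self.name}: cM positions decrease")
        if cm[-1] - cm[0] <= 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be > 0")

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def bp_to_cm(self, bp) -> np.ndarray:
        """Interpolate genetic position; clamps outside the anchored range."""
        return np.interp(np.asarray(bp, dtype=float), self.bp, self.cm)

    def cm_to_bp(self, cm) -> np.ndarray:
        return np.interp(np.asarray(cm, dtype=float), self.cm, self.bp)


@dataclass(frozen=True)
class GeneticMap:
    chroms: tuple[ChromosomeMap, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chroms", tuple(self.chroms))
        names = [c.name for c in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in map")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chroms})

    def __getitem__(self, name: str) -> ChromosomeMap:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genetic map") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chroms]

    @property
    def n_chrom(self) -> int:
        return len(self.chroms)

    @property
    def total_morgans(self) -> float:
        """Haploid genome length in Morgans."""
        return sum(c.length_cm for c in self.chroms) / 100.0

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray:
        return self[chrom].bp_to_cm(bp)

    def marker_table(self, bp_per_cm: float = 1e6) -> pd.DataFrame:
        """Marker grid at the map's anchor points (chrom, pos, id, ref, alt)."""
        frames = []
        for c in self.chroms:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c.name,
                        "pos": c.bp,
                        "id": [f"c{c.name}_m{i}" for i in range(c.bp.size)],
                        "ref": "A",
                        "alt": "G",
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def make_uniform_map(
    n_chrom: int,
    lengths_cm,
    marker_spacing_cm: float,
    bp_per_cm: float = 1e6,
) -> GeneticMap:
    """Build a map with equally spaced anchors and a constant cM/bp rate.

    ``lengths_cm`` may be a scalar (shared by all chromosomes) or a sequence of
    per-chromosome genetic lengths. The realized length of each chromosome is
    the largest multiple of the spacing not exceeding the requested length, so
    it matches the request to within one spacing unit.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if marker_spacing_cm <= 0:
        raise ValueError("marker spacing must be > 0")
    lengths = np.broadcast_to(np.asarray(lengths_cm, dtype=float), (n_chrom,))
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be > 0")
    chroms = []
    for i, length in enumerate(lengths, start=1):
        n_steps = int(np.floor(length / marker_spacing_cm + 1e-6))
        cm = np.arange(n_steps + 1, dtype=float) * marker_spacing_cm
        bp = np.round(cm * bp_per_cm).astype(np.int64) + 1
        chroms.append(ChromosomeMap(name=str(i), bp=bp, cm=cm))
    return GeneticMap(tuple(chroms))


def write_plink_map(gmap: GeneticMap, path) -> None:
    """Write the map anchors as PLINK-style 4-column text (chrom id cM bp)."""
    rows = []
    for c in gmap.chroms:
        for i in range(c.bp.size):
            rows.append((c.name, f"c{c.name}_m{i}", c.cm[i], c.bp[i]))
    df = pd.DataFrame(rows, columns=["chrom", "id", "cm", "bp"])
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.8g")


def read_plink_map(path) -> GeneticMap:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp"],
        dtype={"chrom": str},
    )
    if df.empty:
        raise ValueError(f"empty map file: {path}")
    chroms = []
    for name, grp in df.groupby("chrom", sort=False):
        chroms.append(
            ChromosomeMap(
                name=str(name),
                bp=grp["bp"].to_numpy(np.int64),
                cm=grp["cm"].to_numpy(float),
            )
        )
    return GeneticMap(tuple(chroms))


def chrom_blocks(markers: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Contiguous per-chromosome row ranges ``(chrom, start, stop)`` of a marker table."""
    chroms = markers["chrom"].to_numpy()
    blocks: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            blocks.append((str(chroms[start]), start, i))
            start = i
    seen = [b[0] for b in blocks]
    if len(set(seen)) != len(seen):
        raise ValueError("marker table not sorted by chromosome (chromosome rows not contiguous)")
    return blocks
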