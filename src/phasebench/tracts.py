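"""Ground-truth ancestry tract simulation for two-way admixed haplotypes.

Two generative models are provided:

* :func:`simulate_markov_tracts` — the founder-pool approximation: switch
  points form a Poisson process of rate T per Morgan along each chromosome,
  and the ancestry after each switch (and at the chromosome start) is drawn
  from the founder-pool composition (0 with probability p). Observed
  ancestry-a tracts therefore end at rate T·p_(1−a) per Morgan.

* :func:`simulate_pedigree_tracts` — an explicit depth-T pedigree: each
  meiosis lays down crossovers as a Poisson process of rate 1 per Morgan and
  alternates between the two parental haplotypes; founder haplotypes in
  generation T carry i.i.d. Bernoulli(p) ancestry. Implemented top-down with
  interval-restricted recursion so the cost scales with the number of
  inherited segments rather than the 2^T founders.

Ancestry codes: 0 ("African-like") with proportion p, 1 ("European-like").
Tract coordinates are genetic (cM), half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, chrom_blocks

__all__ = [
    "AncestryTract",
    "HaploidTractSet",
    "SimConfig",
    "founders_required",
    "simulate_markov_tracts",
    "simulate_pedigree_tracts",
    "tracts_to_marker_ancestry",
    "ancestry_fraction",
    "write_tracts_tsv",
    "read_tracts_tsv",
]

_TOL = 1e-9

DEFAULT_CODES = {0: "AFR", 1: "EUR"}


@dataclass(frozen=True)
class AncestryTract:
    """One ancestry tract on one chromosome, genetic coordinates in cM, [start, end)."""

    chrom: str
    start_cm: float
    end_cm: float
    ancestry: int

    def __post_init__(self) -> None:
        if not self.end_cm > self.start_cm:
            raise ValueError(
                f"tract end ({self.end_cm}) must exceed start ({self.start_cm})"
            )
        if self.ancestry not in (0, 1):
            raise ValueError(f"ancestry must be 0 or 1, got {self.ancestry}")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class HaploidTractSet:
    """Ordered, genome-covering tracts for one transmitted haplotype.

    ``tracts`` maps chromosome name to the ordered tract list; after
    canonicalization adjacent tracts have different ancestries and the tracts
    tile [0, L_c] exactly.
    """

    tracts: dict[str, list[AncestryTract]]
    individual: str = ""
    haplotype: int = 0

    def validate_tiling(self, gmap: GeneticMap, tol: float = 1e-6) -> None:
        for name in gmap.names:
            trs = self.tracts.get(name)
            if not trs:
                raise ValueError(f"chromosome {name} has no tracts")
            if abs(trs[0].start_cm) > tol:
                raise ValueError(f"chromosome {name}: first tract does not start at 0")
            if abs(trs[-1].end_cm - gmap[name].length_cm) > tol:
                raise ValueError(f"chromosome {name}: last tract does not end at L_c")
            for a, b in zip(trs, trs[1:]):
                if abs(a.end_cm - b.start_cm) > tol:
                    raise ValueError(f"chromosome {name}: gap/overlap at {a.end_cm}")

    def n_tracts(self) -> int:
        return sum(len(v) for v in self.tracts.values())


@dataclass
class SimConfig:
    """Study-condition bundle for one simulation setting."""

    T: int
    p: float
    n_individuals: int = 30
    model: str = "markov"
    seed: int | None = None
    switch_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if int(self.T) != self.T or self.T < 1:
            raise ValueError("T must be an integer >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.model not in ("markov", "pedigree"):
            raise ValueError("model must be 'markov' or 'pedigree'")
        if not 0.0 <= self.switch_error_rate <= 1.0:
            raise ValueError("switch_error_rate must lie in [0, 1]")


def founders_required(T: int) -> int:
    """Unadmixed founders needed to simulate one admixed individual without
    founder reuse: 2^T individuals in the oldest generation."""
    if T < 1:
        raise ValueError("T must be >= 1")
    return 2**T


def _merge_segments(segs: list[tuple[float, float, int]], chrom: str) -> list[AncestryTract]:
    """Merge adjacent same-ancestry segments into canonical tracts."""
    out: list[AncestryTract] = []
    cur_s, cur_e, cur_a = segs[0]
    for s, e, a in segs[1:]:
        if a == cur_a:
            cur_e = e
        else:
            out.append(AncestryTract(chrom, cur_s, cur_e, cur_a))
            cur_s, cur_e, cur_a = s, e, a
    out.append(AncestryTract(chrom, cur_s, cur_e, cur_a))
    return out


def simulate_markov_tracts(
    gmap: GeneticMap, T: float, p: float, seed=None, individual: str = "", haplotype: int = 0
) -> HaploidTractSet:
    """Simulate one haploid tract set under the founder-pool Markov model.

    Switch points are Poisson with rate ``T`` per Morgan; the ancestry at the
    chromosome start and after every switch is 0 with probability ``p``.
    Same-ancestry neighbours are merged, so observed ancestry-a tracts end at
    rate T·p_(1−a) per Morgan.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tracts: dict[str, list[AncestryTract]] = {}
    for ch in gmap.chroms:
        L = ch.length_cm
        n_switch = rng.poisson(T * L / 100.0)
        xs = np.sort(rng.uniform(0.0, L, n_switch))
        anc = (rng.random(n_switch + 1) >= p).astype(int)  # 0 w.p. p
        bounds = np.concatenate(([0.0], xs, [L]))
        segs = [
            (float(bounds[k]), float(bounds[k + 1]), int(anc[k]))
            for k in range(n_switch + 1)
            if bounds[k + 1] - bounds[k] > _TOL
        ]
        if not segs:  # pathological: all switch points at 0 or L
            segs = [(0.0, float(L), int(anc[0]))]
        segs[0] = (0.0, segs[0][1], segs[0][2])
        segs[-1] = (segs[-1][0], float(L), segs[-1][2])
        tracts[ch.name] = _merge_segments(segs, ch.name)
    return HaploidTractSet(tracts=tracts, individual=individual, haplotype=haplotype)


# -- pedigree model -----------------------------------------------------------

_Interval = tuple[float, float]


def _meiosis_partition(
    intervals: dict[str, list[_Interval]], gmap: GeneticMap, rng: np.random.Generator
) -> tuple[dict[str, list[_Interval]], dict[str, list[_Interval]]]:
    """Split inherited intervals between the two parental haplotypes of one meiosis.

    Crossovers are Poisson with rate 1 per Morgan per chromosome; segments
    alternate between parents starting from a fair-coin choice per chromosome.
    """
    part_a: dict[str, list[_Interval]] = {}
    part_b: dict[str, list[_Interval]] = {}
    for name, ivs in intervals.items():
        L = gmap[name].length_cm
        n_co = rng.poisson(L / 100.0)
        xs = np.sort(rng.uniform(0.0, L, n_co))
        start = int(rng.integers(2))
        bounds = np.concatenate(([0.0], xs, [L]))
        for k in range(bounds.size - 1):
            seg_s, seg_e = float(bounds[k]), float(bounds[k + 1])
            dest = part_a if (start + k) % 2 == 0 else part_b
            for s, e in ivs:
                lo, hi = max(s, seg_s), min(e, seg_e)
                if hi - lo > _TOL:
                    dest.setdefault(name, []).append((lo, hi))
    return part_a, part_b


def _descend(
    intervals: dict[str, list[_Interval]],
    depth: int,
    p: float,
    gmap: GeneticMap,
    rng: np.random.Generator,
    out: dict[str, list[tuple[float, float, int]]],
) -> None:
    if depth == 0:
        anc = 0 if rng.random() < p else 1  # one founder haplotype, one ancestry
        for name, ivs in intervals.items():
            out.setdefault(name, []).extend((s, e, anc) for s, e in ivs)
        return
    part_a, part_b = _meiosis_partition(intervals, gmap, rng)
    for part in (part_a, part_b):
        if part:
            _descend(part, depth - 1, p, gmap, rng, out)


def _pedigree_gamete(
    gmap: GeneticMap, T: int, p: float, rng: np.random.Generator,
    individual: str, haplotype: int,
) -> HaploidTractSet:
    intervals = {ch.name: [(0.0, ch.length_cm)] for ch in gmap.chroms}
    raw: dict[str, list[tuple[float, float, int]]] = {}
    _descend(intervals, T, p, gmap, rng, raw)
    tracts: dict[str, list[AncestryTract]] = {}
    for ch in gmap.chroms:
        segs = sorted(raw[ch.name])
        tracts[ch.name] = _merge_segments(segs, ch.name)
    return HaploidTractSet(tracts=tracts, individual=individual, haplotype=haplotype)


def simulate_pedigree_tracts(
    gmap: GeneticMap, T: int, p: float, seed=None, individual: str = ""
) -> tuple[HaploidTractSet, HaploidTractSet]:
    """Simulate the two transmitted gametes of one admixed individual.

    The individual sits in generation 0 of a pedigree whose oldest generation
    (T) holds unadmixed founders; each transmitted haplotype is the result of
    T successive meioses over an independent ancestor tree (the two parental
    lineages share no ancestors). Founder haplotypes carry i.i.d. Bernoulli(p)
    ancestry-0 labels.
    """
    if int(T) != T or T < 1:
        raise ValueError("pedigree model requires integer T >= 1 (no admixture event at T=0)")
    rng = np.random.default_rng(seed)
    h0 = _pedigree_gamete(gmap, int(T), p, rng, individual, 0)
    h1 = _pedigree_gamete(gmap, int(T), p, rng, individual, 1)
    return h0, h1


# -- rasterization and summaries ----------------------------------------------


def tracts_to_marker_ancestry(
    tset: HaploidTractSet, gmap: GeneticMap, markers: pd.DataFrame
) -> np.ndarray:
    """Assign each marker the ancestry of the tract containing it.

    Markers are located by genetic position; a marker exactly at the
    chromosome's final genetic position joins the last tract (the half-open
    convention applies everywhere else).
    """
    out = np.empty(len(markers), dtype=np.int8)
    for chrom, b0, b1 in chrom_blocks(markers):
        if chrom not in gmap:
            raise ValueError(f"markers on chromosome {chrom!r} absent from the map")
        pos = markers["pos"].to_numpy()[b0:b1]
        ch = gmap[chrom]
        if np.any(pos < ch.bp[0]) or np.any(pos > ch.bp[-1]):
            raise ValueError(
                f"marker physical position outside the mapped range on chromosome {chrom}"
            )
        cm = ch.bp_to_cm(pos)
        trs = tset.tracts.get(chrom)
        if not trs:
            raise ValueError(f"no tracts for chromosome {chrom!r}")
        starts = np.array([t.start_cm for t in trs])
        anc = np.array([t.ancestry for t in trs], dtype=np.int8)
        idx = np.searchsorted(starts, cm, side="right") - 1
        idx = np.clip(idx, 0, len(trs) - 1)
        out[b0:b1] = anc[idx]
    return out


def ancestry_fraction(tset: HaploidTractSet, ancestry: int = 0) -> float:
    """Genome-wide fraction of genetic length carried by ``ancestry``."""
    tot = 0.0
    hit = 0.0
    for trs in tset.tracts.values():
        for t in trs:
            tot += t.length_cm
            if t.ancestry == ancestry:
                hit += t.length_cm
    return hit / tot


# -- text interchange ----------------------------------------------------------


def write_tracts_tsv(tract_sets, path, codes: dict[int, str] | None = None) -> None:
    """Write tract sets in the BED-like dialect (cM coordinates, half-open)."""
    codes = codes or DEFAULT_CODES
    rows = []
    for ts in tract_sets:
        for chrom, trs in ts.tracts.items():
            for t in trs:
                rows.append(
                    (ts.individual, ts.haplotype, chrom, t.start_cm, t.end_cm, t.ancestry)
                )
    df = pd.DataFrame(
        rows, columns=["individual", "haplotype", "chrom", "start_cm", "end_cm", "ancestry"]
    )
    with open(path, "w") as fh:
        fh.write("#ancestry_codes=" + ",".join(f"{k}:{v}" for k, v in sorted(codes.items())) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_tracts_tsv(path) -> list[HaploidTractSet]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#ancestry_codes="):
            raise ValueError(f"{path}: missing #ancestry_codes header")
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "individual": str})
    out = []
    for (ind, hap), grp in df.groupby(["individual", "haplotype"], sort=False):
        tracts: dict[str, list[AncestryTract]] = {}
        for row in grp.itertuples(index=False):
            tracts.setdefault(row.chrom, []).append(
                AncestryTract(row.chrom, row.start_cm, row.end_cm, int(row.ancestry))
            )
        out.append(HaploidTractSet(tracts=tracts, individual=str(ind), haplotype=int(hap)))
    return out
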