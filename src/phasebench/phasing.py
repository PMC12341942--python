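"""Switch-error injection and the switch-error rate (SER) metric.

A switch error is a point between two consecutive heterozygous sites where the
assignment of alleles to haplotypes flips relative to the truth. Injection is
i.i.d. per heterozygous interval — the standard SER generative model — so the
inject→measure round trip is exactly Binomial(n_intervals, rate). SER pools
discordant/total heterozygous pairs across chromosomes and individuals
(pair-weighted, matching per-individual reports averaged with pair weights);
per-individual values are also returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import chrom_blocks
from .genotypes import PhasedGenotypes

__all__ = ["SwitchRecord", "SerResult", "inject_switch_errors", "ser", "apply_switches_to_tracks"]


@dataclass
class SwitchRecord:
    """Realized switch errors for one individual.

    ``flip_after`` holds the global marker indices of the *left* heterozygous
    site of each flipped interval: haplotype labels are exchanged for all
    markers after that site up to the next flip (or chromosome end).
    """

    sample: str
    flip_after: np.ndarray
    n_intervals: int

    def __post_init__(self) -> None:
        self.flip_after = np.asarray(self.flip_after, dtype=np.int64)
        if np.any(np.diff(self.flip_after) <= 0):
            raise ValueError("flip indices must be strictly increasing")

    @property
    def n_flips(self) -> int:
        return int(self.flip_after.size)

    @property
    def realized_rate(self) -> float:
        return self.n_flips / self.n_intervals if self.n_intervals else float("nan")


@dataclass
class SerResult:
    ser: float
    n_pairs: int
    n_discordant: int
    per_individual: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.per_individual.to_csv(path, sep="\t", index=False, float_format="%.6g")


def inject_switch_errors(
    genotypes: PhasedGenotypes, rate: float, seed=None
) -> tuple[PhasedGenotypes, list[SwitchRecord]]:
    """Flip haplotype assignment with probability ``rate`` per het interval.

    Independently for every consecutive pair of heterozygous sites within a
    chromosome, the haplotype labelling flips from the right-hand site until
    the next flip. Homozygous sites and unphased genotype content are
    untouched; only the phase changes.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("switch-error rate must lie in [0, 1]")
    genotypes.require_phased()
    rng = np.random.default_rng(seed)
    out = genotypes.copy()
    blocks = chrom_blocks(genotypes.markers)
    het = genotypes.het_mask()
    records = []
    for s_idx, name in enumerate(genotypes.samples):
        flips_all = []
        n_intervals = 0
        for _, b0, b1 in blocks:
            het_idx = b0 + np.flatnonzero(het[s_idx, b0:b1])
            if het_idx.size < 2:
                continue
            n = het_idx.size - 1
            n_intervals += n
            flips = rng.random(n) < rate
            parity = np.cumsum(flips) % 2  # applies to het sites 1..n
            swap_sites = het_idx[1:][parity == 1]
            tmp = out.haps[s_idx, 0, swap_sites].copy()
            out.haps[s_idx, 0, swap_sites] = out.haps[s_idx, 1, swap_sites]
            out.haps[s_idx, 1, swap_sites] = tmp
            flips_all.append(het_idx[:-1][flips])
        flip_after = (
            np.concatenate(flips_all) if flips_all else np.empty(0, dtype=np.int64)
        )
        records.append(SwitchRecord(sample=name, flip_after=np.sort(flip_after), n_intervals=n_intervals))
    return out, records


def apply_switches_to_tracks(
    tracks: np.ndarray, record: SwitchRecord, markers: pd.DataFrame
) -> np.ndarray:
    """Propagate genotype switch errors onto per-haplotype ancestry tracks.

    ``tracks`` has shape (2, n_markers); markers strictly after each flip
    point (within its chromosome) have their haplotype assignment exchanged —
    what a perfect phase-based caller would report on the mis-phased input.
    """
    tracks = np.asarray(tracks)
    parity = np.zeros(tracks.shape[1], dtype=np.int8)
    blocks = chrom_blocks(markers)
    bounds = np.array([b1 for _, _, b1 in blocks])
    starts = np.array([b0 for _, b0, _ in blocks])
    for i in record.flip_after:
        k = int(np.searchsorted(starts, i, side="right") - 1)
        parity[i + 1 : bounds[k]] ^= 1
    swapped = tracks.copy()
    mask = parity == 1
    swapped[0, mask] = tracks[1, mask]
    swapped[1, mask] = tracks[0, mask]
    return swapped


def _check_comparable(truth: PhasedGenotypes, test: PhasedGenotypes) -> None:
    if truth.samples != test.samples:
        raise ValueError("SER undefined: sample lists differ")
    if not truth.markers[["chrom", "pos"]].equals(test.markers[["chrom", "pos"]]):
        raise ValueError("SER undefined: marker grids differ")
    truth.require_phased()
    test.require_phased()
    same_content = (truth.haps.sum(axis=1) == test.haps.sum(axis=1)).all()
    if not same_content:
        raise ValueError("SER undefined: genotype content differs between inputs")


def ser(truth: PhasedGenotypes, test: PhasedGenotypes) -> SerResult:
    """Switch-error rate of ``test`` phasing relative to ``truth``.

    Per individual and chromosome, consecutive heterozygous pairs whose
    relative phase orientation disagrees between the two phasings are counted;
    the pooled rate is total discordant pairs / total pairs.
    """
    _check_comparable(truth, test)
    blocks = chrom_blocks(truth.markers)
    het = truth.het_mask()
    rows = []
    tot_pairs = 0
    tot_disc = 0
    for s_idx, name in enumerate(truth.samples):
        n_pairs = 0
        n_disc = 0
        for _, b0, b1 in blocks:
            idx = b0 + np.flatnonzero(het[s_idx, b0:b1])
            if idx.size < 2:
                continue
            orient = truth.haps[s_idx, 0, idx] == test.haps[s_idx, 0, idx]
            disc = orient[:-1] != orient[1:]
            n_pairs += idx.size - 1
            n_disc += int(disc.sum())
        rows.append((name, n_pairs, n_disc, n_disc / n_pairs if n_pairs else float("nan")))
        tot_pairs += n_pairs
        tot_disc += n_disc
    per_ind = pd.DataFrame(rows, columns=["individual", "n_pairs", "n_discordant", "ser"])
    overall = tot_disc / tot_pairs if tot_pairs else float("nan")
    return SerResult(ser=overall, n_pairs=tot_pairs, n_discordant=tot_disc, per_individual=per_ind)
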