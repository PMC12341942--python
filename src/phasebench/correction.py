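"""Ancestry-driven phase correction (TRACTOR-style).

A switch error inside a region where the two haplotypes carry different
ancestries shows up as *both* haplotype tracks changing ancestry in opposite
directions at (nearly) the same position. Scanning left to right, every such
double switch triggers an exchange of the haplotype assignment — of the
ancestry calls and of the underlying genotypes — from the detected point
onward. Switches inside ancestry-homozygous regions are invisible to this
signal and are not attempted; the correction therefore never changes the
diploid ancestry dosage at any marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calls import PhasedAncestryCalls
from .genmap import chrom_blocks
from .genotypes import PhasedGenotypes

__all__ = ["CorrectionRecord", "correct_phase"]


@dataclass
class CorrectionRecord:
    """Detected double-switch events for one individual (global marker indices)."""

    sample: str
    positions: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("corrected positions must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.positions)


def _swap_from(arr2: np.ndarray, j: int, stop: int) -> None:
    tmp = arr2[0, j:stop].copy()
    arr2[0, j:stop] = arr2[1, j:stop]
    arr2[1, j:stop] = tmp


def correct_phase(
    calls: PhasedAncestryCalls,
    genotypes: PhasedGenotypes | None = None,
    window: int = 1,
) -> tuple[PhasedAncestryCalls, PhasedGenotypes | None, list[CorrectionRecord]]:
    """Detect opposite double ancestry switches and rephase downstream.

    ``window`` is the maximum separation, in markers, between the two tracks'
    switch points for them to count as one event (1 = simultaneous only, the
    default since the underlying error flips both at the same site). Applying
    the correction twice equals applying it once.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if genotypes is not None:
        if len(genotypes.markers) != len(calls.markers) or not genotypes.markers[
            ["chrom", "pos"]
        ].equals(calls.markers[["chrom", "pos"]]):
            raise ValueError("calls and genotypes must share one marker grid")
        if genotypes.samples != calls.samples:
            raise ValueError("calls and genotypes must cover the same samples")
    fixed = calls.copy()
    fixed_gt = genotypes.copy() if genotypes is not None else None
    blocks = chrom_blocks(calls.markers)
    records = []
    for i, name in enumerate(calls.samples):
        positions: list[int] = []
        for _, b0, b1 in blocks:
            w = fixed.tracks[i]  # view; swaps below mutate in place
            j = b0 + 1
            while j < b1:
                c0 = w[0, j] != w[0, j - 1]
                c1 = w[1, j] != w[1, j - 1]
                if c0 and c1 and w[0, j] == w[1, j - 1] and w[1, j] == w[0, j - 1]:
                    _swap_from(w, j, b1)
                    if fixed_gt is not None:
                        _swap_from(fixed_gt.haps[i], j, b1)
                    positions.append(j)
                    j += 1
                    continue
                if window > 1 and (c0 != c1):
                    lead, other = (0, 1) if c0 else (1, 0)
                    x, y = w[lead, j - 1], w[lead, j]
                    j2 = None
                    for k in range(j + 1, min(j + window, b1)):
                        if w[lead, k] != w[lead, k - 1]:
                            break  # lead switched again first: not a clean double switch
                        if w[other, k] != w[other, k - 1]:
                            if w[other, k - 1] == y and w[other, k] == x:
                                j2 = k
                            break
                    if j2 is not None:
                        _swap_from(w, j2, b1)
                        if fixed_gt is not None:
                            _swap_from(fixed_gt.haps[i], j2, b1)
                        positions.append(j2)
                        j = j2 + 1
                        continue
                j += 1
        records.append(CorrectionRecord(sample=name, positions=positions))
    return fixed, fixed_gt, records
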