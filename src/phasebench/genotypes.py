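"""Converting ancestry tracts into phased genotypes by panel allele copying.

For each ground-truth tract, one reference haplotype of the matching ancestry
is drawn uniformly from the panel (redrawn independently at every tract
boundary) and its alleles are copied across the tract's markers — the segment
sampling scheme of haplotype-copying admixture simulators. Ground-truth phase
is the assignment of the two tract sets to haplotypes 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vcfio
from .genmap import GeneticMap, chrom_blocks
from .panels import HaplotypePanel
from .tracts import HaploidTractSet

__all__ = ["PhasedGenotypes", "synthesize", "concat_genotypes", "write_vcf", "read_vcf"]


@dataclass
class PhasedGenotypes:
    """Diploid genotypes with haplotype assignment and per-site phase flags."""

    markers: pd.DataFrame
    samples: list[str]
    haps: np.ndarray  # (n_samples, 2, n_markers), alleles in {0, 1}
    phased: np.ndarray  # (n_samples, n_markers) bool

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        self.phased = np.asarray(self.phased, dtype=bool)
        n, two, m = self.haps.shape
        if two != 2 or m != len(self.markers) or n != len(self.samples):
            raise ValueError("haplotype array shape does not match samples/markers")
        if self.phased.shape != (n, m):
            raise ValueError("phase-flag array shape mismatch")
        if self.haps.size and self.haps.max() > 1:
            raise ValueError("alleles must be in {0, 1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def het_mask(self) -> np.ndarray:
        return self.haps[:, 0, :] != self.haps[:, 1, :]

    def dosage(self) -> np.ndarray:
        return self.haps.sum(axis=1)

    def require_phased(self) -> None:
        if not self.phased.all():
            raise ValueError("operation requires fully phased genotypes")

    def copy(self) -> "PhasedGenotypes":
        return PhasedGenotypes(
            markers=self.markers,
            samples=list(self.samples),
            haps=self.haps.copy(),
            phased=self.phased.copy(),
        )

    def equal(self, other: "PhasedGenotypes") -> bool:
        return (
            self.samples == other.samples
            and self.markers[["chrom", "pos"]].equals(other.markers[["chrom", "pos"]])
            and np.array_equal(self.haps, other.haps)
            and np.array_equal(self.phased, other.phased)
        )


def synthesize(
    tracts0: HaploidTractSet,
    tracts1: HaploidTractSet,
    panels: tuple[HaplotypePanel, HaplotypePanel],
    gmap: GeneticMap,
    seed=None,
    sample: str = "sim_0_0",
) -> PhasedGenotypes:
    """Copy panel alleles over the two tract sets of one admixed individual."""
    by_anc = {pan.ancestry: pan for pan in panels}
    if set(by_anc) != {0, 1}:
        raise ValueError("need one panel per ancestry (0 and 1)")
    if not by_anc[0].markers[["chrom", "pos"]].equals(by_anc[1].markers[["chrom", "pos"]]):
        raise ValueError("panels do not share a marker table")
    markers = by_anc[0].markers
    rng = np.random.default_rng(seed)
    m = len(markers)
    haps = np.zeros((1, 2, m), dtype=np.uint8)
    blocks = chrom_blocks(markers)
    for hap_idx, tset in ((0, tracts0), (1, tracts1)):
        for chrom, b0, b1 in blocks:
            if chrom not in tset.tracts:
                raise ValueError(f"tract set missing chromosome {chrom!r}")
            cm = gmap.bp_to_cm(chrom, markers["pos"].to_numpy()[b0:b1])
            trs = tset.tracts[chrom]
            for k, t in enumerate(trs):
                panel = by_anc[t.ancestry]
                if panel.n_hap == 0:
                    raise ValueError(f"empty panel for required ancestry {t.ancestry}")
                donor = int(rng.integers(panel.n_hap))
                i0 = int(np.searchsorted(cm, t.start_cm, side="left"))
                i1 = b1 - b0 if k == len(trs) - 1 else int(
                    np.searchsorted(cm, t.end_cm, side="left")
                )
                haps[0, hap_idx, b0 + i0 : b0 + i1] = panel.haps[donor, b0 + i0 : b0 + i1]
    return PhasedGenotypes(
        markers=markers,
        samples=[sample],
        haps=haps,
        phased=np.ones((1, m), dtype=bool),
    )


def concat_genotypes(parts: list[PhasedGenotypes]) -> PhasedGenotypes:
    """Stack per-individual genotypes sharing one marker table into a cohort."""
    if not parts:
        raise ValueError("nothing to concatenate")
    markers = parts[0].markers
    for p in parts[1:]:
        if not p.markers[["chrom", "pos"]].equals(markers[["chrom", "pos"]]):
            raise ValueError("marker tables differ between cohort members")
    return PhasedGenotypes(
        markers=markers,
        samples=[s for p in parts for s in p.samples],
        haps=np.concatenate([p.haps for p in parts], axis=0),
        phased=np.concatenate([p.phased for p in parts], axis=0),
    )


def write_vcf(genotypes: PhasedGenotypes, path) -> None:
    vcfio.write_phased_vcf(
        path, genotypes.markers, genotypes.samples, genotypes.haps, genotypes.phased
    )


def read_vcf(path) -> PhasedGenotypes:
    markers, samples, haps, phased = vcfio.read_phased_vcf(path)
    return PhasedGenotypes(markers=markers, samples=samples, haps=haps, phased=phased)
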