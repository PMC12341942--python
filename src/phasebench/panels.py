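"""Synthetic ancestral haplotype panels under the Balding–Nichols model.

The two panels stand in for diverged reference populations (e.g. West African
and European panels). Per marker, an ancestral frequency q ~ Uniform(0.05,
0.95) is drawn, each population's frequency follows
Beta(q(1−FST)/FST, (1−q)(1−FST)/FST) — so Var(q_a | q) = FST·q(1−q) — and
haplotype alleles are i.i.d. Bernoulli(q_a). Markers are unlinked within
panels; background LD is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from . import vcfio

__all__ = [
    "HaplotypePanel",
    "balding_nichols_freqs",
    "simulate_panels",
    "write_panel_vcf",
    "read_panel_vcf",
]

DEFAULT_FST = 0.15  # typical continental African–European differentiation


@dataclass
class HaplotypePanel:
    """Ancestry-labelled phased reference haplotypes.

    ``haps`` is a (n_haplotypes, n_markers) binary matrix; ``markers`` holds
    chrom, pos, id, ref, alt and is shared (byte-identical) between the two
    panels of a pair.
    """

    ancestry: int
    markers: pd.DataFrame
    haps: np.ndarray

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.ndim != 2 or self.haps.shape[1] != len(self.markers):
            raise ValueError("haplotype matrix shape does not match marker table")
        if self.haps.size and self.haps.max() > 1:
            raise ValueError("alleles must be in {0, 1}")

    @property
    def n_hap(self) -> int:
        return self.haps.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.haps.mean(axis=0)


def balding_nichols_freqs(q, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Draw population frequencies around ancestral ``q``: Beta with
    Var(q_a | q) = FST·q·(1−q)."""
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie strictly in (0, 1)")
    q = np.asarray(q, dtype=float)
    scale = (1.0 - fst) / fst
    return rng.beta(q * scale, (1.0 - q) * scale)


def simulate_panels(
    gmap: GeneticMap,
    n_hap_per_pop: int,
    fst: float = DEFAULT_FST,
    seed=None,
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Simulate two diverged panels sharing one marker table.

    Markers sit on the map's anchor grid. Draw order (ancestral q, then the
    two population frequencies, then each panel's alleles) is fixed, so a
    given seed always yields identical panels.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie strictly in (0, 1)")
    if n_hap_per_pop < 2:
        raise ValueError("need at least 2 haplotypes per population")
    rng = np.random.default_rng(seed)
    markers = gmap.marker_table()
    m = len(markers)
    q = rng.uniform(0.05, 0.95, m)
    q0 = balding_nichols_freqs(q, fst, rng)
    q1 = balding_nichols_freqs(q, fst, rng)
    haps0 = (rng.random((n_hap_per_pop, m)) < q0).astype(np.uint8)
    haps1 = (rng.random((n_hap_per_pop, m)) < q1).astype(np.uint8)
    return (
        HaplotypePanel(ancestry=0, markers=markers, haps=haps0),
        HaplotypePanel(ancestry=1, markers=markers, haps=haps1),
    )


def write_panel_vcf(panel: HaplotypePanel, path, sample_prefix: str | None = None) -> None:
    """Write a panel as a phased VCF, two haplotypes per synthetic sample."""
    if panel.n_hap % 2 != 0:
        raise ValueError("panel VCF export requires an even number of haplotypes")
    prefix = sample_prefix or f"pop{panel.ancestry}"
    n_samp = panel.n_hap // 2
    samples = [f"{prefix}_{i}" for i in range(n_samp)]
    haps = panel.haps.reshape(n_samp, 2, -1)
    vcfio.write_phased_vcf(path, panel.markers, samples, haps)


def read_panel_vcf(path, ancestry: int) -> HaplotypePanel:
    markers, samples, haps, phased = vcfio.read_phased_vcf(path)
    if not phased.all():
        raise ValueError(f"{path}: panel VCF must be fully phased")
    flat = haps.reshape(haps.shape[0] * 2, haps.shape[2])
    return HaplotypePanel(ancestry=ancestry, markers=markers, haps=flat)
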