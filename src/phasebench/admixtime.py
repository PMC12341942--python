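"""Time since admixture from phased local-ancestry tracts.

Under a single-pulse founder-pool model, tract lengths of ancestry a are
exponential with rate λ_a = p_(1−a)·T per Morgan, censored at chromosome ends.
Per individual, pooling both haplotypes' tracts:

    λ̂_a = (N_a − m_a) / Σ_i x_{i,a}        (censored-exponential rate MLE)
    p̂_a = Σ_i x_{i,a} / Σ_a' Σ_i x_{i,a'}   (denominator = 2L for a diploid)
    T̂   = ½ (λ̂_0 / p̂_1 + λ̂_1 / p̂_0)

where N_a counts tracts of ancestry a, m_a those cut off by a chromosome's
right end (whose terminating crossover is unobserved), and x_{i,a} are Morgan
lengths. Single-ancestry individuals yield a flagged, missing estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import PhasedAncestryCalls
from .genmap import GeneticMap, chrom_blocks
from .tracts import AncestryTract, HaploidTractSet

__all__ = [
    "TractStats",
    "TimeEstimate",
    "extract_tracts",
    "tract_stats",
    "lambda_hat",
    "p_hat",
    "t_hat_phased",
    "estimate_time",
    "deviation_report",
]


@dataclass
class TractStats:
    """Per-ancestry tract counts and Morgan lengths for one individual.

    Arrays are indexed by ancestry a ∈ {0, 1}. ``n_terminal[a]`` counts
    right-end chromosome tracts (≤ n_chrom per haplotype); with both
    haplotypes pooled the total tract length equals 2L Morgans.
    """

    n_tracts: np.ndarray
    n_terminal: np.ndarray
    total_len_morgans: np.ndarray
    genome_length_morgans: float
    n_chrom: int
    n_haplotypes: int


@dataclass
class TimeEstimate:
    lambda0: float
    lambda1: float
    p0: float
    p1: float
    t_hat: float
    degenerate: bool = False
    reason: str = ""


def extract_tracts(
    calls: PhasedAncestryCalls, gmap: GeneticMap
) -> list[tuple[HaploidTractSet, HaploidTractSet]]:
    """Turn marker-level phased calls into canonical tract sets.

    Maximal constant-ancestry runs become tracts; each boundary is placed at
    the genetic midpoint between the last marker of one run and the first of
    the next. The first tract starts at 0 and the last ends at L_c.
    """
    markers = calls.markers
    blocks = chrom_blocks(markers)
    for chrom, _, _ in blocks:
        if chrom not in gmap:
            raise ValueError(f"markers on chromosome {chrom!r} are not on the map")
    cm_by_block = {
        chrom: gmap.bp_to_cm(chrom, markers["pos"].to_numpy()[b0:b1])
        for chrom, b0, b1 in blocks
    }
    out = []
    for i, name in enumerate(calls.samples):
        pair = []
        for h in (0, 1):
            tracts: dict[str, list[AncestryTract]] = {}
            for chrom, b0, b1 in blocks:
                v = calls.tracks[i, h, b0:b1]
                cm = cm_by_block[chrom]
                L = gmap[chrom].length_cm
                change = np.flatnonzero(v[1:] != v[:-1]) + 1
                bounds = [0.0] + [float((cm[j - 1] + cm[j]) / 2.0) for j in change] + [L]
                anc_vals = v[np.concatenate(([0], change))]
                tracts[chrom] = [
                    AncestryTract(chrom, bounds[k], bounds[k + 1], int(anc_vals[k]))
                    for k in range(len(anc_vals))
                ]
            pair.append(HaploidTractSet(tracts, individual=name, haplotype=h))
        out.append((pair[0], pair[1]))
    return out


def tract_stats(
    tract_sets: Sequence[HaploidTractSet], gmap: GeneticMap
) -> TractStats:
    """Count tracts, right-end censored tracts, and Morgan lengths.

    Accepts one haploid tract set (per-haplotype diagnostics) or both of an
    individual's haplotypes (the default estimation unit).
    """
    n = np.zeros(2, dtype=np.int64)
    m_term = np.zeros(2, dtype=np.int64)
    sumx = np.zeros(2, dtype=float)
    for ts in tract_sets:
        ts.validate_tiling(gmap)
        for chrom in gmap.names:
            trs = ts.tracts[chrom]
            for t in trs:
                n[t.ancestry] += 1
                sumx[t.ancestry] += t.length_cm / 100.0
            m_term[trs[-1].ancestry] += 1
    return TractStats(
        n_tracts=n,
        n_terminal=m_term,
        total_len_morgans=sumx,
        genome_length_morgans=gmap.total_morgans,
        n_chrom=gmap.n_chrom,
        n_haplotypes=len(tract_sets),
    )


def lambda_hat(stats: TractStats, a: int, censor: bool = True) -> float:
    """Censored-exponential rate MLE for switching out of ancestry ``a``.

    ``censor=False`` drops the −m_a correction (for demonstrating the
    chromosome-end bias); Σx = 0 yields NaN (undefined, never zero).
    """
    sx = stats.total_len_morgans[a]
    if sx <= 0.0:
        return float("nan")
    k = stats.n_tracts[a] - (stats.n_terminal[a] if censor else 0)
    return float(k / sx)


def p_hat(stats: TractStats) -> tuple[float, float]:
    """Ancestry fractions from total tract length; sums to 1 by construction."""
    tot = stats.total_len_morgans.sum()
    if tot <= 0.0:
        raise ValueError("total tract length is zero")
    p0 = float(stats.total_len_morgans[0] / tot)
    return p0, 1.0 - p0


def t_hat_phased(lambda0: float, lambda1: float, p0: float, p1: float) -> float:
    """Average of the two one-ancestry solutions of λ_a = p_(1−a)·T."""
    return 0.5 * (lambda0 / p1 + lambda1 / p0)


def estimate_time(stats: TractStats, censor: bool = True) -> TimeEstimate:
    """Full per-individual pipeline: rates, fractions, and T̂ with degeneracy flags."""
    p0, p1 = p_hat(stats)
    l0 = lambda_hat(stats, 0, censor=censor)
    l1 = lambda_hat(stats, 1, censor=censor)
    if p0 <= 0.0 or p1 <= 0.0 or np.isnan(l0) or np.isnan(l1):
        return TimeEstimate(
            lambda0=l0, lambda1=l1, p0=p0, p1=p1, t_hat=float("nan"),
            degenerate=True, reason="single-ancestry genome: rate/fraction undefined",
        )
    return TimeEstimate(
        lambda0=l0, lambda1=l1, p0=p0, p1=p1, t_hat=t_hat_phased(l0, l1, p0, p1)
    )


def deviation_report(
    estimates: Sequence[TimeEstimate],
    t_true: float,
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-individual T̂ − T_true table plus cohort summary.

    Degenerate estimates are excluded from the mean and counted.
    """
    names = list(samples) if samples is not None else [str(i) for i in range(len(estimates))]
    df = pd.DataFrame(
        {
            "individual": names,
            "t_hat": [e.t_hat for e in estimates],
            "deviation": [e.t_hat - t_true for e in estimates],
            "degenerate": [e.degenerate for e in estimates],
        }
    )
    ok = df.loc[~df["degenerate"], "deviation"]
    summary = {
        "t_true": t_true,
        "n": int(len(df)),
        "n_degenerate": int(df["degenerate"].sum()),
        "mean_t_hat": float(df.loc[~df["degenerate"], "t_hat"].mean()) if len(ok) else float("nan"),
        "mean_deviation": float(ok.mean()) if len(ok) else float("nan"),
    }
    return df, summary
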