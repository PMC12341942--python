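"""Diploid LAI accuracy: Pearson correlation of concatenated ancestry dosages.

Inferred and true dosages over all markers of all individuals are laid out
sequentially in two vectors and scored with Pearson's R — a phase-free metric,
so relabeling haplotype tracks before collapsing never changes it. Probabilistic
callers are scored through the expected dosage E[a] = Σ_a P(a)·a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import DiploidAncestryCalls

__all__ = ["AccuracyResult", "expected_dosage", "pearson_r"]


@dataclass
class AccuracyResult:
    r: float
    n_markers: int
    n_individuals: int
    undefined: bool = False
    per_individual: pd.DataFrame | None = None


def expected_dosage(calls: DiploidAncestryCalls) -> np.ndarray:
    """Per-marker expected ancestry-1 dosage; hard calls pass through unchanged."""
    if calls.is_hard:
        return calls.dosage.astype(float)
    return calls.posterior @ np.array([0.0, 1.0, 2.0])


def _as_matrix(calls) -> np.ndarray:
    if isinstance(calls, DiploidAncestryCalls):
        return expected_dosage(calls)
    return np.asarray(calls, dtype=float)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan"), True  # undefined, reported as missing rather than 0
    return float(stats.pearsonr(x, y)[0]), False


def pearson_r(
    inferred, truth: DiploidAncestryCalls, per_individual: bool = False
) -> AccuracyResult:
    """Pearson R between inferred and true dosages, pooled across individuals.

    ``inferred`` may be hard calls, posterior calls, or a dosage/expectation
    matrix; ``truth`` must be hard calls. A constant vector makes the
    correlation undefined — flagged, never coerced to 0.
    """
    if not truth.is_hard:
        raise ValueError("truth must be hard diploid calls")
    a_inf = _as_matrix(inferred)
    a_true = np.asarray(truth.dosage, dtype=float)
    if a_inf.shape != a_true.shape:
        raise ValueError(
            f"shape mismatch: inferred {a_inf.shape} vs truth {a_true.shape}"
        )
    r, undef = _pearson(a_inf.ravel(), a_true.ravel())
    per_ind = None
    if per_individual:
        rows = []
        for i, s in enumerate(truth.samples):
            ri, ui = _pearson(a_inf[i], a_true[i])
            rows.append((s, ri, ui))
        per_ind = pd.DataFrame(rows, columns=["individual", "r", "undefined"])
    return AccuracyResult(
        r=r,
        n_markers=a_true.shape[1],
        n_individuals=a_true.shape[0],
        undefined=undef,
        per_individual=per_ind,
    )
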