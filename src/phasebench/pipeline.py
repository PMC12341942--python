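"""Config-driven orchestration of the full benchmarking grid.

One grid cell = (T, p, switch rate, replicate). Each cell simulates a cohort
of admixed individuals, synthesizes phased genotypes from the panels, injects
switch errors, derives the phase-based oracle calls implied by the corrupted
phase, optionally applies phase correction, and scores SER, diploid Pearson R,
and tract-based admixture-time deviations. Every cell's randomness derives
deterministically from (master seed, cell index), so cells are independent and
individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calls as calls_mod
from .admixtime import deviation_report, estimate_time, extract_tracts, tract_stats
from .calls import PhasedAncestryCalls, collapse_to_diploid, oracle_lai, read_calls_tsv, read_msp
from .correction import correct_phase
from .genmap import GeneticMap, make_uniform_map
from .genotypes import concat_genotypes, synthesize
from .metrics import pearson_r
from .panels import simulate_panels
from .phasing import apply_switches_to_tracks, inject_switch_errors, ser
from .tracts import simulate_markov_tracts, simulate_pedigree_tracts

__all__ = ["GridConfig", "run_grid", "import_external_calls"]

_PANEL_KEY = 1 << 20  # spawn key reserved for panel simulation


@dataclass
class GridConfig:
    """Experimental grid definition; defaults mirror the study conditions
    (3 replicates of 30 individuals per cell, FST 0.15 panels)."""

    t_values: list[int] = field(default_factory=lambda: [5, 6, 7])
    p_values: list[float] = field(default_factory=lambda: [0.2, 0.5, 0.8])
    switch_rates: list[float] = field(default_factory=lambda: [0.0, 0.03])
    n_replicates: int = 3
    n_individuals: int = 30
    model: str = "markov"
    n_chrom: int = 22
    chrom_length_cm: float = 163.2
    marker_spacing_cm: float = 0.2
    n_hap_per_pop: int = 70
    fst: float = 0.15
    correction: bool = False
    correction_window: int = 1
    lai_miscall_prob: float = 0.0
    lai_jitter_cm: float = 0.0
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def make_map(self) -> GeneticMap:
        return make_uniform_map(self.n_chrom, self.chrom_length_cm, self.marker_spacing_cm)

    def cells(self) -> list[tuple[int, int, float, float, int]]:
        out = []
        idx = 0
        for T in self.t_values:
            for p in self.p_values:
                for rate in self.switch_rates:
                    for rep in range(self.n_replicates):
                        out.append((idx, T, p, rate, rep))
                        idx += 1
        return out


def _cell_seed(master_seed: int, cell_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index,))


def run_cell(
    cfg: GridConfig,
    gmap: GeneticMap,
    panels,
    T: int,
    p: float,
    rate: float,
    rep: int,
    cell_index: int,
) -> dict:
    """Simulate, corrupt, call, (fix,) score and estimate one grid cell."""
    rng = np.random.default_rng(_cell_seed(cfg.master_seed, cell_index))
    markers = panels[0].markers
    truth_pairs = []
    gt_parts = []
    for i in range(cfg.n_individuals):
        name = f"sim_{rep}_{i}"
        if cfg.model == "markov":
            ts0 = simulate_markov_tracts(gmap, T, p, rng, individual=name, haplotype=0)
            ts1 = simulate_markov_tracts(gmap, T, p, rng, individual=name, haplotype=1)
        else:
            ts0, ts1 = simulate_pedigree_tracts(gmap, T, p, rng, individual=name)
        truth_pairs.append((ts0, ts1))
        gt_parts.append(synthesize(ts0, ts1, panels, gmap, rng, sample=name))
    gt_true = concat_genotypes(gt_parts)
    truth_calls = oracle_lai(truth_pairs, gmap, markers, mode="perfect")

    gt_obs, switch_records = inject_switch_errors(gt_true, rate, rng)
    obs_tracks = np.stack(
        [
            apply_switches_to_tracks(truth_calls.tracks[i], rec, markers)
            for i, rec in enumerate(switch_records)
        ]
    )
    obs_calls = PhasedAncestryCalls(
        markers=markers, samples=list(truth_calls.samples), tracks=obs_tracks
    )
    if cfg.lai_miscall_prob > 0 or cfg.lai_jitter_cm > 0:
        noisy = oracle_lai(
            extract_tracts(obs_calls, gmap),
            gmap,
            markers,
            mode="corrupted",
            jitter_cm=cfg.lai_jitter_cm,
            miscall_prob=cfg.lai_miscall_prob,
            seed=rng,
            samples=list(obs_calls.samples),
        )
        obs_calls = noisy

    ser_raw = ser(gt_true, gt_obs).ser
    if cfg.correction:
        obs_calls, gt_obs, _ = correct_phase(obs_calls, gt_obs, window=cfg.correction_window)
    ser_final = ser(gt_true, gt_obs).ser

    acc = pearson_r(collapse_to_diploid(obs_calls), collapse_to_diploid(truth_calls))
    estimates = [
        estimate_time(tract_stats(pair, gmap)) for pair in extract_tracts(obs_calls, gmap)
    ]
    _, summary = deviation_report(estimates, float(T), samples=list(obs_calls.samples))
    return {
        "T": T,
        "p": p,
        "switch_rate": rate,
        "replicate": rep,
        "n_individuals": cfg.n_individuals,
        "ser_injected": ser_raw,
        "ser": ser_final,
        "r": acc.r,
        "mean_t_hat": summary["mean_t_hat"],
        "mean_deviation": summary["mean_deviation"],
        "n_degenerate": summary["n_degenerate"],
    }


def run_grid(cfg: GridConfig, outdir=None) -> pd.DataFrame:
    """Run every grid cell; on per-cell failure, log and continue.

    Returns one summary row per (T, p, rate, replicate). If ``outdir`` is
    given, writes ``summary.tsv`` and ``summary.json`` there (byte-identical
    across reruns of the same config).
    """
    gmap = cfg.make_map()
    panels = simulate_panels(
        gmap,
        cfg.n_hap_per_pop,
        cfg.fst,
        seed=np.random.SeedSequence(entropy=cfg.master_seed, spawn_key=(_PANEL_KEY,)),
    )
    rows = []
    failures = []
    for idx, T, p, rate, rep in cfg.cells():
        try:
            rows.append(run_cell(cfg, gmap, panels, T, p, rate, rep, idx))
        except Exception as exc:  # cell independence: keep going
            failures.append({"cell": idx, "T": T, "p": p, "switch_rate": rate,
                             "replicate": rep, "error": str(exc)})
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.8g")
        payload = {"config": asdict(cfg), "rows": json.loads(df.to_json(orient="records")),
                   "failures": failures}
        (outdir / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    if failures:
        raise RuntimeError(
            f"{len(failures)} grid cell(s) failed: {failures}"
        )
    return df


def import_external_calls(
    path,
    fmt: str,
    truth_calls: PhasedAncestryCalls,
    gmap: GeneticMap,
    t_true: float | None = None,
) -> dict:
    """Score an external LAI output file with the same metrics as internal calls.

    ``fmt`` is ``"msp"``, ``"tsv"`` or ``"vcf"``. The file must cover exactly
    the truth marker grid; a mismatch is rejected with a diff summary.
    """
    if fmt == "msp":
        ext = read_msp(path, truth_calls.markers)
    elif fmt == "tsv":
        ext = read_calls_tsv(path)
    elif fmt == "vcf":
        ext = calls_mod.read_anc_vcf(path)
    else:
        raise ValueError(f"unknown calls format {fmt!r}")
    if len(ext.markers) != len(truth_calls.markers) or not ext.markers[
        ["chrom", "pos"]
    ].reset_index(drop=True).equals(truth_calls.markers[["chrom", "pos"]].reset_index(drop=True)):
        raise ValueError(
            "marker grid mismatch: external file has "
            f"{len(ext.markers)} markers vs truth {len(truth_calls.markers)}"
        )
    if ext.samples != truth_calls.samples:
        raise ValueError("sample mismatch between external calls and truth")
    acc = pearson_r(collapse_to_diploid(ext), collapse_to_diploid(truth_calls))
    estimates = [estimate_time(tract_stats(pair, gmap)) for pair in extract_tracts(ext, gmap)]
    row = {
        "source": str(path),
        "format": fmt,
        "r": acc.r,
        "n_markers": acc.n_markers,
        "mean_t_hat": float(np.nanmean([e.t_hat for e in estimates])),
    }
    if t_true is not None:
        _, summary = deviation_report(estimates, t_true, samples=list(ext.samples))
        row["mean_deviation"] = summary["mean_deviation"]
    return row
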