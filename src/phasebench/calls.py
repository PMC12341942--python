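"""Local-ancestry call containers, an oracle/stub caller, and format readers.

The oracle caller rasterizes ground-truth tracts (perfect mode) or degrades
them with boundary jitter, whole-tract miscalls and haplotype-track switch
errors (corrupted mode), standing in for external LAI tools so the downstream
scoring and time-estimation stages are testable end to end. Readers cover
RFMix v2 ``.msp.tsv`` window files and VCFs that carry per-haplotype ancestry
codes in FORMAT fields (FLARE-style), plus an internal wide-TSV dialect.

Ancestry code 1 is "European" by convention: diploid dosage counts ancestry-1
haplotypes. The code map travels in file headers to prevent silent relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vcfio
from .genmap import GeneticMap, chrom_blocks
from .tracts import DEFAULT_CODES, AncestryTract, HaploidTractSet, tracts_to_marker_ancestry

__all__ = [
    "PhasedAncestryCalls",
    "DiploidAncestryCalls",
    "oracle_lai",
    "collapse_to_diploid",
    "read_msp",
    "write_msp",
    "read_anc_vcf",
    "write_anc_vcf",
    "read_calls_tsv",
    "write_calls_tsv",
]


@dataclass
class PhasedAncestryCalls:
    """Per-marker ancestry on two haplotype tracks per individual."""

    markers: pd.DataFrame
    samples: list[str]
    tracks: np.ndarray  # (n_samples, 2, n_markers) int8
    codes: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CODES))

    def __post_init__(self) -> None:
        self.tracks = np.asarray(self.tracks, dtype=np.int8)
        n, two, m = self.tracks.shape
        if two != 2 or n != len(self.samples) or m != len(self.markers):
            raise ValueError("track array shape does not match samples/markers")
        if self.tracks.size and not np.isin(self.tracks, list(self.codes)).all():
            raise ValueError("ancestry code outside the declared code set")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "PhasedAncestryCalls":
        return PhasedAncestryCalls(
            self.markers, list(self.samples), self.tracks.copy(), dict(self.codes)
        )


@dataclass
class DiploidAncestryCalls:
    """Unphased ancestry dosage (count of ancestry-1 haplotypes), hard or probabilistic."""

    markers: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray | None = None  # (n_samples, n_markers) in {0,1,2}
    posterior: np.ndarray | None = None  # (n_samples, n_markers, 3), rows sum to 1

    def __post_init__(self) -> None:
        if (self.dosage is None) == (self.posterior is None):
            raise ValueError("provide exactly one of dosage or posterior")
        if self.dosage is not None:
            self.dosage = np.asarray(self.dosage)
            if not np.isin(self.dosage, (0, 1, 2)).all():
                raise ValueError("hard dosage calls must lie in {0, 1, 2}")
        else:
            self.posterior = np.asarray(self.posterior, dtype=float)
            if self.posterior.shape[-1] != 3 or np.any(self.posterior < 0):
                raise ValueError("posterior must be nonnegative over {0,1,2}")
            if np.max(np.abs(self.posterior.sum(axis=-1) - 1.0)) > 1e-6:
                raise ValueError("posterior rows must sum to 1 (tolerance 1e-6)")

    @property
    def is_hard(self) -> bool:
        return self.dosage is not None


def collapse_to_diploid(calls: PhasedAncestryCalls) -> DiploidAncestryCalls:
    """Phase-free dosage: count of ancestry-1 haplotypes per marker."""
    dosage = (calls.tracks == 1).sum(axis=1).astype(np.int8)
    return DiploidAncestryCalls(markers=calls.markers, samples=list(calls.samples), dosage=dosage)


# -- oracle caller -------------------------------------------------------------


def _jitter_tracts(
    tset: HaploidTractSet, jitter_cm: float, rng: np.random.Generator
) -> HaploidTractSet:
    out: dict[str, list[AncestryTract]] = {}
    for chrom, trs in tset.tracts.items():
        if len(trs) == 1:
            out[chrom] = list(trs)
            continue
        bounds = [t.start_cm for t in trs] + [trs[-1].end_cm]
        for k in range(1, len(bounds) - 1):
            lo = bounds[k - 1]
            hi = trs[k].end_cm
            b = bounds[k] + rng.normal(0.0, jitter_cm)
            bounds[k] = min(max(b, lo + 1e-9), hi - 1e-9)
        out[chrom] = [
            AncestryTract(chrom, bounds[k], bounds[k + 1], trs[k].ancestry)
            for k in range(len(trs))
        ]
    return HaploidTractSet(out, tset.individual, tset.haplotype)


def _miscall_tracts(
    tset: HaploidTractSet, prob: float, rng: np.random.Generator
) -> HaploidTractSet:
    out: dict[str, list[AncestryTract]] = {}
    for chrom, trs in tset.tracts.items():
        out[chrom] = [
            AncestryTract(
                chrom, t.start_cm, t.end_cm, 1 - t.ancestry if rng.random() < prob else t.ancestry
            )
            for t in trs
        ]
    return HaploidTractSet(out, tset.individual, tset.haplotype)


def oracle_lai(
    truth: list[tuple[HaploidTractSet, HaploidTractSet]],
    gmap: GeneticMap,
    markers: pd.DataFrame,
    mode: str = "perfect",
    jitter_cm: float = 0.0,
    miscall_prob: float = 0.0,
    switch_rate: float = 0.0,
    seed=None,
    samples: list[str] | None = None,
) -> PhasedAncestryCalls:
    """Rasterize truth tracts into marker-level calls, optionally degraded.

    ``corrupted`` mode independently (i) jitters each interior tract boundary
    by Normal(0, jitter_cm), (ii) flips whole-tract ancestry with
    ``miscall_prob``, and (iii) exchanges the two haplotype tracks at each
    marker interval with probability ``switch_rate``.
    """
    if mode not in ("perfect", "corrupted"):
        raise ValueError("mode must be 'perfect' or 'corrupted'")
    if min(jitter_cm, miscall_prob, switch_rate) < 0:
        raise ValueError("corruption parameters must be nonnegative")
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = [
            pair[0].individual or f"sim_0_{i}" for i, pair in enumerate(truth)
        ]
    m = len(markers)
    tracks = np.zeros((len(truth), 2, m), dtype=np.int8)
    blocks = chrom_blocks(markers)
    for i, (ts0, ts1) in enumerate(truth):
        for h, ts in ((0, ts0), (1, ts1)):
            if mode == "corrupted":
                if jitter_cm > 0:
                    ts = _jitter_tracts(ts, jitter_cm, rng)
                if miscall_prob > 0:
                    ts = _miscall_tracts(ts, miscall_prob, rng)
            tracks[i, h] = tracts_to_marker_ancestry(ts, gmap, markers)
        if mode == "corrupted" and switch_rate > 0:
            for _, b0, b1 in blocks:
                flips = rng.random(b1 - b0 - 1) < switch_rate
                parity = (np.cumsum(flips) % 2).astype(bool)
                cols = b0 + 1 + np.flatnonzero(parity)
                tracks[i, :, cols] = tracks[i, ::-1, cols]
    return PhasedAncestryCalls(markers=markers, samples=samples, tracks=tracks)


# -- RFMix v2 msp.tsv ----------------------------------------------------------


def write_msp(calls: PhasedAncestryCalls, path, gmap: GeneticMap | None = None) -> None:
    """Write calls as an RFMix v2-style ``.msp.tsv`` window file."""
    markers = calls.markers
    pos = markers["pos"].to_numpy()
    lines = []
    for chrom, b0, b1 in chrom_blocks(markers):
        block = calls.tracks[:, :, b0:b1]  # (n, 2, w)
        flat = block.reshape(-1, b1 - b0)
        change = np.flatnonzero((flat[:, 1:] != flat[:, :-1]).any(axis=0)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [b1 - b0]))
        cm = gmap.bp_to_cm(chrom, pos[b0:b1]) if gmap is not None and chrom in gmap else None
        for s, e in zip(starts, stops):
            spos = int(pos[b0 + s])
            epos = int(pos[b0 + e]) if e < b1 - b0 else int(pos[b1 - 1]) + 1
            sg = float(cm[s]) if cm is not None else 0.0
            eg = float(cm[e - 1]) if cm is not None else 0.0
            row = [chrom, spos, epos, f"{sg:.6g}", f"{eg:.6g}", e - s]
            row += [int(v) for v in flat[:, s]]
            lines.append("\t".join(str(x) for x in row))
    with open(path, "w") as fh:
        fh.write(
            "#Subpopulation order/codes: "
            + "\t".join(f"{name}={code}" for code, name in sorted(calls.codes.items()))
            + "\n"
        )
        cols = ["#chm", "spos", "epos", "sgpos", "egpos", "n snps"]
        cols += [f"{s}.{h}" for s in calls.samples for h in (0, 1)]
        fh.write("\t".join(cols) + "\n")
        fh.write("\n".join(lines) + "\n")


def read_msp(path, markers: pd.DataFrame) -> PhasedAncestryCalls:
    """Expand an ``.msp.tsv`` window file onto a marker grid.

    Windows are half-open in physical position ([spos, epos)); a marker
    covered by no window, an overlapping window, or an undeclared ancestry
    code is a parse error.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#Subpopulation order/codes:"):
            raise ValueError(f"{path}: missing subpopulation code header")
        codes: dict[int, str] = {}
        for tok in first.split(":", 1)[1].split():
            name, code = tok.rsplit("=", 1)
            codes[int(code)] = name
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=header, dtype={"chm": str})
    hap_cols = header[6:]
    samples = list(dict.fromkeys(c.rsplit(".", 1)[0] for c in hap_cols))
    m = len(markers)
    tracks = np.full((len(samples), 2, m), -1, dtype=np.int8)
    pos = markers["pos"].to_numpy()
    chrom_arr = markers["chrom"].to_numpy()
    for row in df.itertuples(index=False):
        sel = np.flatnonzero(
            (chrom_arr == row.chm) & (pos >= row.spos) & (pos < row.epos)
        )
        if np.any(tracks[0, 0, sel] != -1):
            raise ValueError(f"{path}: overlapping windows on chromosome {row.chm}")
        vals = np.array(row[6:], dtype=np.int8).reshape(len(samples), 2)
        if not np.isin(vals, list(codes)).all():
            raise ValueError(f"{path}: unknown ancestry code in window {row.chm}:{row.spos}")
        tracks[:, :, sel] = vals[:, :, None]
    if np.any(tracks == -1):
        raise ValueError(f"{path}: markers not covered by any window")
    return PhasedAncestryCalls(markers=markers, samples=samples, tracks=tracks, codes=codes)


# -- VCF with per-haplotype ancestry FORMAT fields ----------------------------


def write_anc_vcf(
    calls: PhasedAncestryCalls, path, genotypes=None, fields: tuple[str, str] = ("AN1", "AN2")
) -> None:
    """Write calls as a VCF carrying per-haplotype ancestry codes in FORMAT fields."""
    if genotypes is not None:
        haps, phased = genotypes.haps, genotypes.phased
    else:
        n, _, m = calls.tracks.shape
        haps = np.zeros((n, 2, m), dtype=np.uint8)
        phased = np.ones((n, m), dtype=bool)
    vcfio.write_phased_vcf(
        path,
        calls.markers,
        calls.samples,
        haps,
        phased,
        format_fields={fields[0]: calls.tracks[:, 0, :], fields[1]: calls.tracks[:, 1, :]},
    )


def read_anc_vcf(
    path, fields: tuple[str, str] = ("AN1", "AN2"), codes: dict[int, str] | None = None
) -> PhasedAncestryCalls:
    markers, samples, _, _, extra = vcfio.read_phased_vcf(path, format_fields=fields)
    tracks = np.stack([extra[fields[0]], extra[fields[1]]], axis=1).astype(np.int8)
    return PhasedAncestryCalls(
        markers=markers, samples=samples, tracks=tracks, codes=codes or dict(DEFAULT_CODES)
    )


# -- internal wide-TSV dialect -------------------------------------------------


def write_calls_tsv(calls: PhasedAncestryCalls, path) -> None:
    df = calls.markers[["chrom", "pos"]].copy()
    for i, s in enumerate(calls.samples):
        df[f"{s}.0"] = calls.tracks[i, 0]
        df[f"{s}.1"] = calls.tracks[i, 1]
    with open(path, "w") as fh:
        fh.write(
            "#ancestry_codes=" + ",".join(f"{k}:{v}" for k, v in sorted(calls.codes.items())) + "\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_calls_tsv(path) -> PhasedAncestryCalls:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#ancestry_codes="):
            raise ValueError(f"{path}: missing #ancestry_codes header")
        codes = {
            int(tok.split(":")[0]): tok.split(":")[1]
            for tok in first.split("=", 1)[1].split(",")
        }
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    samples = list(dict.fromkeys(c.rsplit(".", 1)[0] for c in hap_cols))
    tracks = np.stack(
        [
            np.stack([df[f"{s}.0"].to_numpy(np.int8), df[f"{s}.1"].to_numpy(np.int8)])
            for s in samples
        ]
    )
    return PhasedAncestryCalls(
        markers=df[["chrom", "pos"]], samples=samples, tracks=tracks, codes=codes
    )
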