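"""Phased-VCF text I/O shared by panels, genotypes and ancestry-call readers.

Writing emits plain VCF 4.2 text directly; reading goes through cyvcf2.
Only biallelic 0/1 sites without missing data are supported, matching the
simulator's output domain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_phased_vcf", "read_phased_vcf"]

_GT_PHASED = np.array(["0|0", "0|1", "1|0", "1|1"])
_GT_UNPHASED = np.array(["0/0", "0/1", "1/0", "1/1"])


def _header_lines(markers: pd.DataFrame, extra_format: list[str] | None = None) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=phasebench"]
    for chrom in dict.fromkeys(markers["chrom"]):
        max_pos = int(markers.loc[markers["chrom"] == chrom, "pos"].max())
        lines.append(f"##contig=<ID={chrom},length={max_pos + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.extend(extra_format or [])
    return lines


def write_phased_vcf(
    path,
    markers: pd.DataFrame,
    samples: list[str],
    haps: np.ndarray,
    phased: np.ndarray | None = None,
    format_fields: dict[str, np.ndarray] | None = None,
) -> None:
    """Write genotypes as VCF text.

    ``haps`` has shape (n_samples, 2, n_markers) with alleles in {0, 1};
    ``phased`` (n_samples, n_markers) selects ``|`` vs ``/`` separators and
    defaults to fully phased. ``format_fields`` adds integer per-haplotype
    FORMAT columns (e.g. ancestry codes), each of shape (n_samples, n_markers).
    """
    haps = np.asarray(haps, dtype=np.int64)
    n_samples, _, m = haps.shape
    if len(samples) != n_samples or m != len(markers):
        raise ValueError("sample/marker dimensions do not match haplotype array")
    codes = haps[:, 0, :] * 2 + haps[:, 1, :]
    if phased is None:
        gt = _GT_PHASED[codes]
    else:
        gt = np.where(np.asarray(phased, bool), _GT_PHASED[codes], _GT_UNPHASED[codes])
    fmt_names = ["GT"]
    cols = gt
    if format_fields:
        parts = [gt]
        for name, arr in format_fields.items():
            fmt_names.append(name)
            parts.append(np.asarray(arr).astype(str))
        cols = parts[0]
        for extra in parts[1:]:
            cols = np.char.add(np.char.add(cols, ":"), extra)
    extra_defs = [
        f'##FORMAT=<ID={n},Number=1,Type=Integer,Description="Per-haplotype ancestry code">'
        for n in fmt_names[1:]
    ]
    body = pd.DataFrame(
        {
            "#CHROM": markers["chrom"].to_numpy(),
            "POS": markers["pos"].to_numpy(),
            "ID": markers["id"].to_numpy() if "id" in markers else ".",
            "REF": markers["ref"].to_numpy() if "ref" in markers else "A",
            "ALT": markers["alt"].to_numpy() if "alt" in markers else "G",
            "QUAL": ".",
            "FILTER": ".",
            "INFO": ".",
            "FORMAT": ":".join(fmt_names),
        }
    )
    for i, s in enumerate(samples):
        body[s] = cols[i]
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(markers, extra_defs)) + "\n")
        body.to_csv(fh, sep="\t", index=False)


def read_phased_vcf(path, format_fields: tuple[str, ...] = ()):
    """Read a VCF into (markers, samples, haps, phased[, fields]).

    Raises ``ValueError`` on malformed input, naming the file and, where
    available, the failing record.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise ValueError(f"failed to parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    h0, h1, ph = [], [], []
    extra: dict[str, list] = {name: [] for name in format_fields}
    try:
        for var in vcf:
            gts = var.genotypes
            if any(len(g) != 3 or g[0] < 0 or g[1] < 0 for g in gts):
                raise ValueError(
                    f"{path}: missing or non-diploid genotype at {var.CHROM}:{var.POS}"
                )
            rows.append(
                (str(var.CHROM), int(var.POS), var.ID or ".", var.REF, (var.ALT or ["."])[0])
            )
            h0.append([g[0] for g in gts])
            h1.append([g[1] for g in gts])
            ph.append([bool(g[2]) for g in gts])
            for name in format_fields:
                arr = var.format(name)
                if arr is None:
                    raise ValueError(f"{path}: FORMAT field {name} absent at {var.CHROM}:{var.POS}")
                extra[name].append(arr[:, 0])
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"failed to parse VCF {path}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no variant records")
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    haps = np.stack(
        [np.asarray(h0, dtype=np.uint8).T, np.asarray(h1, dtype=np.uint8).T], axis=1
    )  # (n_samples, 2, m)
    phased = np.asarray(ph, dtype=bool).T
    if format_fields:
        fields = {
            name: np.asarray(vals, dtype=np.int16).T for name, vals in extra.items()
        }
        return markers, samples, haps, phased, fields
    return markers, samples, haps, phased
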