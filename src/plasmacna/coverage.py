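"""Bin-level coverage, control baseline and per-bin Z-scores.

The score for bin b of a sample against a panel of controls is

    z_b = (norm_b - mean(controls_b)) / sd(controls_b)

computed on depth-normalized coverage (each sample scaled so its genome
mean over usable bins is 1). The SD uses the n-1 denominator by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import GenomeBins

RATIO_FLOOR = 1e-6  # norm values clamped here before log2

__all__ = [
    "CoverageProfile",
    "ControlBaseline",
    "ZProfile",
    "bin_reads",
    "depth_normalize",
    "build_baseline",
    "zscore",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass(frozen=True)
class CoverageProfile:
    """One sample's per-bin read counts, optionally depth-normalized."""

    sample_id: str
    raw: np.ndarray
    n_reads_total: int = 0
    norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw)
        if (raw < 0).any():
            raise ValueError("raw counts must be non-negative")
        object.__setattr__(self, "raw", raw)
        if self.norm is not None:
            object.__setattr__(self, "norm", np.asarray(self.norm, dtype=float))

    def __len__(self) -> int:
        return len(self.raw)


@dataclass(frozen=True)
class ControlBaseline:
    """Per-bin mean/SD of control normalized coverage plus a usability mask."""

    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    mask: np.ndarray

    def __len__(self) -> int:
        return len(self.mean)

    def to_frame(self, bins: GenomeBins) -> pd.DataFrame:
        t = bins.table[["chrom", "start", "end"]].copy()
        t["mean"] = self.mean
        t["sd"] = self.sd
        t["mask"] = self.mask.astype(int)
        return t


@dataclass(frozen=True)
class ZProfile:
    """Per-bin Z-scores and log2 ratios; masked bins are NaN."""

    sample_id: str
    z: np.ndarray
    ratio: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return len(self.z)

    def to_frame(self, bins: GenomeBins) -> pd.DataFrame:
        t = bins.table[["chrom", "start", "end", "arm"]].copy()
        t["z"] = self.z
        t["ratio"] = self.ratio
        t["mask"] = self.mask.astype(int)
        return t


def bin_reads(alignment_path, bins: GenomeBins, min_mapq: int = 20,
              sample_id: str | None = None) -> CoverageProfile:
    """Count primary, non-duplicate read 5' starts per bin from a SAM/BAM.

    Reads are streamed (no index needed); secondary, supplementary,
    unmapped, QC-fail and duplicate reads are skipped, as are reads below
    ``min_mapq``. Strand is ignored: the 5' start of a reverse read is its
    rightmost aligned base.
    """
    import pysam

    raw = np.zeros(len(bins), dtype=np.int64)
    starts_by_chrom = {
        chrom: (bins.starts[bins.chrom_slice(chrom)], bins.chrom_slice(chrom).start)
        for chrom in bins.chroms
    }
    bin_size = bins.bin_size
    try:
        af = pysam.AlignmentFile(str(alignment_path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot open alignment file {alignment_path}: {exc}") from exc
    with af:
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.is_qcfail):
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            entry = starts_by_chrom.get(chrom)
            if entry is None:
                continue
            starts, offset = entry
            pos = read.reference_end - 1 if read.is_reverse else read.reference_start
            b = pos // bin_size
            if 0 <= b < len(starts):
                raw[offset + b] += 1
    sid = sample_id or str(alignment_path)
    return CoverageProfile(sample_id=sid, raw=raw, n_reads_total=int(raw.sum()))


def depth_normalize(profile: CoverageProfile,
                    mask: np.ndarray | None = None) -> CoverageProfile:
    """Scale raw counts so the mean over unmasked bins is exactly 1."""
    raw = profile.raw.astype(float)
    if mask is None:
        mask = np.ones(len(raw), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != raw.shape:
        raise ValueError("mask shape does not match profile")
    m = raw[mask].mean() if mask.any() else 0.0
    if m <= 0:
        raise ValueError(f"profile {profile.sample_id!r} has no usable coverage")
    return replace(profile, norm=raw / m)


def build_baseline(controls: list[CoverageProfile], sd_floor: float = 0.05,
                   ddof: int = 1) -> ControlBaseline:
    """Per-bin mean and SD of normalized control coverage.

    Bins with zero mean, zero SD, or SD below ``sd_floor`` times the median
    SD are masked out. ``ddof=1`` gives the sample (n-1) SD; set ``ddof=0``
    for the population denominator.
    """
    if len(controls) < 2:
        raise ValueError("baseline needs at least 2 controls")
    lengths = {len(c) for c in controls}
    if len(lengths) != 1:
        raise ValueError(f"controls have mismatched bin frames: lengths {lengths}")
    mat = np.vstack([
        c.norm if c.norm is not None else depth_normalize(c).norm for c in controls
    ])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=ddof)
    median_sd = np.median(sd[sd > 0]) if (sd > 0).any() else 0.0
    mask = (mean > 0) & (sd > 0) & (sd >= sd_floor * median_sd)
    return ControlBaseline(mean=mean, sd=sd, n_controls=len(controls), mask=mask)


def zscore(profile: CoverageProfile, baseline: ControlBaseline) -> ZProfile:
    """Score one depth-normalized sample against the control baseline."""
    if profile.norm is None:
        raise ValueError("profile must be depth-normalized before scoring")
    if len(profile) != len(baseline):
        raise ValueError(
            f"frame mismatch: profile has {len(profile)} bins, "
            f"baseline has {len(baseline)}"
        )
    mask = baseline.mask
    z = np.full(len(profile), np.nan)
    ratio = np.full(len(profile), np.nan)
    norm = profile.norm
    z[mask] = (norm[mask] - baseline.mean[mask]) / baseline.sd[mask]
    ratio[mask] = np.log2(np.maximum(norm[mask], RATIO_FLOOR) / baseline.mean[mask])
    return ZProfile(sample_id=profile.sample_id, z=z, ratio=ratio, mask=mask.copy())


def read_counts_tsv(path, bins: GenomeBins,
                    sample_id: str | None = None) -> CoverageProfile:
    """Read a bin-count TSV (chrom, start, end, count) aligned to ``bins``."""
    t = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "count"}
    if not required <= set(t.columns):
        raise ValueError(f"counts TSV must have columns {sorted(required)}")
    if len(t) != len(bins):
        raise ValueError(
            f"counts TSV has {len(t)} rows but frame has {len(bins)} bins"
        )
    ref = bins.table
    if not ((t["chrom"].to_numpy() == ref["chrom"].to_numpy()).all()
            and (t["start"].to_numpy() == ref["start"].to_numpy()).all()):
        raise ValueError("counts TSV bin coordinates do not match the frame")
    raw = t["count"].to_numpy()
    sid = sample_id or str(path)
    return CoverageProfile(sample_id=sid, raw=raw, n_reads_total=int(raw.sum()))


def write_counts_tsv(profile: CoverageProfile, bins: GenomeBins, path) -> None:
    t = bins.table[["chrom", "start", "end"]].copy()
    t["count"] = profile.raw
    t.to_csv(path, sep="\t", index=False)
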