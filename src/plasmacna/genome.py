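"""Binned genome coordinate frame.

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates appear only in exported SEG files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 200_000

__all__ = [
    "Karyotype",
    "GenomeBins",
    "load_default_karyotype",
    "make_bins",
    "assign_arms",
]


@dataclass(frozen=True)
class Karyotype:
    """Chromosome lengths and centromere midpoints.

    ``table`` columns: chrom, length, centromere_mid, included (bool).
    Sex chromosomes are excluded by default (mixed-sex cohorts make their
    coverage bimodal against a pooled baseline).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "length", "centromere_mid"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"karyotype missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ValueError("karyotype is empty")
        if (t["length"] <= 0).any():
            raise ValueError("chromosome lengths must be positive")
        bad = (t["centromere_mid"] <= 0) | (t["centromere_mid"] >= t["length"])
        if bad.any():
            raise ValueError(
                "centromere_mid must lie strictly inside (0, length): "
                f"{t.loc[bad, 'chrom'].tolist()}"
            )
        if "included" not in t.columns:
            object.__setattr__(
                self, "table", t.assign(included=True).reset_index(drop=True)
            )
        else:
            t = t.copy()
            t["included"] = t["included"].astype(bool)
            object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def chroms(self) -> list[str]:
        """Names of included chromosomes, in table order."""
        t = self.table
        return t.loc[t["included"], "chrom"].tolist()

    def length_of(self, chrom: str) -> int:
        return int(self._row(chrom)["length"])

    def centromere_of(self, chrom: str) -> int:
        return int(self._row(chrom)["centromere_mid"])

    def _row(self, chrom: str) -> pd.Series:
        sel = self.table[self.table["chrom"] == chrom]
        if len(sel) == 0:
            raise KeyError(f"chromosome {chrom!r} not in karyotype")
        return sel.iloc[0]

    @classmethod
    def from_tsv(cls, path) -> "Karyotype":
        t = pd.read_csv(path, sep="\t")
        if "included" in t.columns:
            t["included"] = t["included"].astype(bool)
        return cls(t)

    def to_tsv(self, path) -> None:
        t = self.table.copy()
        t["included"] = t["included"].astype(int)
        t.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GenomeBins:
    """Ordered fixed-width genomic bins with arm labels.

    ``table`` columns: chrom, start, end, bin_index, arm. ``bin_index`` is
    dense and zero-based over the whole frame.
    """

    table: pd.DataFrame
    bin_size: int
    _chrom_slices: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        slices: dict[str, slice] = {}
        for chrom, grp in t.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            slices[str(chrom)] = slice(int(idx[0]), int(idx[-1]) + 1)
        object.__setattr__(self, "_chrom_slices", slices)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        """Positional slice of this chromosome's bins (bins are genome-ordered)."""
        try:
            return self._chrom_slices[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} has no bins") from None

    @property
    def starts(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    @property
    def arms(self) -> np.ndarray:
        return self.table["arm"].to_numpy()

    def to_bed(self, path) -> None:
        self.table[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def load_default_karyotype(include_sex: bool = False) -> Karyotype:
    """Load the bundled hg19-like autosome karyotype.

    With ``include_sex=True`` chrX/chrY are flagged included as well.
    """
    ref = importlib.resources.files("plasmacna") / "data" / "karyotype_hg19.tsv"
    with importlib.resources.as_file(ref) as path:
        kt = Karyotype.from_tsv(path)
    if include_sex:
        t = kt.table.copy()
        t["included"] = True
        kt = Karyotype(t)
    return kt


def make_bins(karyotype: Karyotype, bin_size: int = DEFAULT_BIN_SIZE) -> GenomeBins:
    """Tile every included chromosome with fixed-width bins.

    Each chromosome gets ``ceil(length / bin_size)`` bins; the final bin is
    truncated at the chromosome end. Deterministic in the karyotype order.
    """
    if bin_size < 10_000:
        raise ValueError(f"bin_size must be >= 10000, got {bin_size}")
    chroms = karyotype.chroms
    if not chroms:
        raise ValueError("karyotype has no included chromosomes")
    frames = []
    for chrom in chroms:
        length = karyotype.length_of(chrom)
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    table = pd.concat(frames, ignore_index=True)
    table["bin_index"] = np.arange(len(table), dtype=np.int64)
    bins = GenomeBins(table=table, bin_size=int(bin_size))
    return assign_arms(bins, karyotype)


def assign_arms(bins: GenomeBins, karyotype: Karyotype) -> GenomeBins:
    """Label each bin p/q by its midpoint relative to the centromere.

    Midpoints exactly at the centromere go to q (fixed tie rule).
    """
    t = bins.table.copy()
    mid = (t["start"].to_numpy() + t["end"].to_numpy()) // 2
    arms = np.empty(len(t), dtype=object)
    for chrom in t["chrom"].unique():
        cen = karyotype.centromere_of(str(chrom))  # KeyError if absent
        sel = (t["chrom"] == chrom).to_numpy()
        arms[sel] = np.where(mid[sel] < cen, "p", "q")
    t["arm"] = arms
    return GenomeBins(table=t, bin_size=bins.bin_size)
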