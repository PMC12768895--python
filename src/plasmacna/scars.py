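"""HRD scoring: count of large genomic alterations (LGAs).

An LGA is a copy-level break between two directly adjacent segments on the
same chromosome arm, where both flanking segments span at least
``min_size`` (default 10 Mb) and their mean log2 ratios differ by at least
``delta_min``. Segments shorter than ``smooth_size`` are first merged into
the neighbor with the closer mean so that small interstitial noise does
not break adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Karyotype
from .segment import SegmentSet

MIN_SIZE = 10_000_000
SMOOTH_SIZE = 3_000_000
DELTA_MIN = 0.1

__all__ = ["ScarScore", "lga_count"]


@dataclass(frozen=True)
class ScarScore:
    sample_id: str
    lga_count: int
    qualifying_breaks: tuple  # (chrom, position, left_len, right_len, delta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.qualifying_breaks),
            columns=["chrom", "position", "left_len", "right_len", "delta"],
        )


def _smooth(segs: list[dict], smooth_size: int) -> list[dict]:
    """Merge sub-threshold segments into the closer-mean neighbor."""
    segs = [dict(s) for s in segs]
    while len(segs) > 1:
        lengths = [s["end_bp"] - s["start_bp"] for s in segs]
        small = [k for k, ln in enumerate(lengths) if ln < smooth_size]
        if not small:
            break
        k = min(small, key=lambda k: lengths[k])  # smallest first, deterministic
        left = segs[k - 1] if k > 0 else None
        right = segs[k + 1] if k + 1 < len(segs) else None
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            dl = abs(segs[k]["mean"] - left["mean"])
            dr = abs(segs[k]["mean"] - right["mean"])
            target = left if dl <= dr else right
        w1, w2 = target["n_bins"], segs[k]["n_bins"]
        target["mean"] = (target["mean"] * w1 + segs[k]["mean"] * w2) / (w1 + w2)
        target["n_bins"] = w1 + w2
        target["start_bp"] = min(target["start_bp"], segs[k]["start_bp"])
        target["end_bp"] = max(target["end_bp"], segs[k]["end_bp"])
        segs.pop(k)
    return segs


def lga_count(segments: SegmentSet, karyotype: Karyotype | None = None,
              min_size: int = MIN_SIZE, delta_min: float = DELTA_MIN,
              smooth_size: int = SMOOTH_SIZE) -> ScarScore:
    """Count qualifying large-alteration breaks genome-wide.

    When a karyotype is given, breaks whose flanks straddle the centromere
    (flank midpoints on different arms) are excluded; without one, every
    within-chromosome adjacency is eligible.
    """
    t = segments.table
    if len(t) == 0:
        return ScarScore(segments.sample_id, 0, ())
    value_col = "mean_ratio" if "mean_ratio" in t.columns else "mean_value"
    breaks = []
    for chrom, grp in t.groupby("chrom", sort=False):
        grp = grp.sort_values("start_bin")
        segs = [
            {
                "start_bp": int(r.start_bp),
                "end_bp": int(r.end_bp),
                "mean": float(getattr(r, value_col)),
                "n_bins": int(r.n_bins),
            }
            for r in grp.itertuples()
        ]
        segs = _smooth(segs, smooth_size)
        cen = karyotype.centromere_of(str(chrom)) if karyotype is not None else None
        for left, right in zip(segs[:-1], segs[1:]):
            left_len = left["end_bp"] - left["start_bp"]
            right_len = right["end_bp"] - right["start_bp"]
            if left_len < min_size or right_len < min_size:
                continue
            delta = abs(left["mean"] - right["mean"])
            if delta < delta_min:
                continue
            if cen is not None:
                mid_l = (left["start_bp"] + left["end_bp"]) // 2
                mid_r = (right["start_bp"] + right["end_bp"]) // 2
                if (mid_l < cen) != (mid_r < cen):
                    continue  # break straddles the centromere
            breaks.append(
                (str(chrom), int(right["start_bp"]), int(left_len),
                 int(right_len), float(delta))
            )
    return ScarScore(segments.sample_id, len(breaks), tuple(breaks))
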