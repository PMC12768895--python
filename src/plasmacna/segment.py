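"""Circular binary segmentation with permutation significance.

Each chromosome is treated as a circle; the best split is the arc boundary
pair (i, j] maximizing the absolute two-sample t-statistic between the arc
and its complement. A split is accepted when its permutation p-value is
below ``alpha``, then both sides are segmented recursively. Adjacent
segments whose means differ by less than ``undo_sd`` pooled within-segment
SDs are merged back afterwards.

Only the arc structure within a chromosome is circular; chromosomes are
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import ZProfile
from .genome import GenomeBins

__all__ = [
    "SegmentationParams",
    "SegmentSet",
    "max_circular_t",
    "split_p_value",
    "segment_profile",
    "segment_values",
    "merge_undo",
    "write_seg",
]

_NO_SPLIT = (-1, -1, 0.0)
_VAR_EPS = 1e-12


def _max_t_py(x, min_width):  # pragma: no cover - numba-compiled twin below
    n = x.shape[0]
    bi, bj, bt = -1, -1, 0.0
    if n < 2 * min_width:
        return bi, bj, bt
    S = np.empty(n + 1)
    Q = np.empty(n + 1)
    S[0] = 0.0
    Q[0] = 0.0
    for i in range(n):
        S[i + 1] = S[i] + x[i]
        Q[i + 1] = Q[i] + x[i] * x[i]
    tot = S[n]
    qtot = Q[n]
    for i in range(n):
        jhi = i + (n - min_width)
        if jhi > n:
            jhi = n
        if i > 0 and jhi == n:
            jhi = n - 1  # (i, n) duplicates the split (0, i)
        for j in range(i + min_width, jhi + 1):
            k = j - i
            m1 = (S[j] - S[i]) / k
            m2 = (tot - (S[j] - S[i])) / (n - k)
            ssw = qtot - k * m1 * m1 - (n - k) * m2 * m2
            if ssw < 0.0:
                ssw = 0.0
            d = m1 - m2
            if n > 2:
                denom = (ssw / (n - 2)) * (1.0 / k + 1.0 / (n - k))
            else:
                denom = 0.0
            if denom < _VAR_EPS:
                t = 0.0 if d * d < _VAR_EPS else 1e12
            else:
                t = math.sqrt(d * d / denom)
            if t > bt:
                bt = t
                bi = i
                bj = j
    return bi, bj, bt


try:  # numba speeds the O(n^2) split search ~50x; plain numpy works without it
    from numba import njit

    _max_t_impl = njit(cache=True)(_max_t_py)

    @njit(cache=True)
    def _perm_exceed_numba(x, t_obs, n_perm, min_width, seed,
                           stop_exceed, min_accept, stop_m):
        np.random.seed(seed)
        y = x.copy()
        done = 0
        exceed = 0
        for _ in range(n_perm):
            np.random.shuffle(y)
            _, _, t = _max_t_impl(y, min_width)
            done += 1
            if t >= t_obs:
                exceed += 1
            if stop_exceed > 0 and exceed >= stop_exceed:
                break
            if exceed < stop_m.shape[0] and done <= stop_m[exceed]:
                break  # exceedance rate provably above alpha already
            if min_accept > 0 and done >= min_accept and exceed == 0:
                break
        return done, exceed

    _perm_exceed_impl = _perm_exceed_numba
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _max_t_numpy(x, min_width):
        n = len(x)
        if n < 2 * min_width:
            return _NO_SPLIT
        S = np.concatenate(([0.0], np.cumsum(x)))
        qtot = float(np.sum(x * x))
        tot = S[n]
        idx = np.arange(n + 1)
        K = (idx[None, :] - idx[:, None]).astype(float)
        valid = (K >= min_width) & (K <= n - min_width)
        valid[1:, n] = False  # (i, n) duplicates the split (0, i)
        with np.errstate(divide="ignore", invalid="ignore"):
            A = S[None, :] - S[:, None]
            m1 = A / K
            m2 = (tot - A) / (n - K)
            ssw = qtot - K * m1**2 - (n - K) * m2**2
            np.clip(ssw, 0.0, None, out=ssw)
            d2 = (m1 - m2) ** 2
            denom = (ssw / max(n - 2, 1)) * (1.0 / K + 1.0 / (n - K))
            t = np.sqrt(d2 / denom)
        t[denom < _VAR_EPS] = np.where(
            d2[denom < _VAR_EPS] < _VAR_EPS, 0.0, 1e12
        )
        t[~valid] = -1.0
        flat = int(np.argmax(t))
        i, j = divmod(flat, n + 1)
        bt = float(t[i, j])
        if bt <= 0.0:
            return _NO_SPLIT
        return i, j, bt

    _max_t_impl = _max_t_numpy

    def _perm_exceed_numpy(x, t_obs, n_perm, min_width, seed,
                           stop_exceed, min_accept, stop_m):
        rng = np.random.default_rng(seed)
        done = 0
        exceed = 0
        for _ in range(n_perm):
            y = rng.permutation(x)
            _, _, t = _max_t_numpy(y, min_width)
            done += 1
            if t >= t_obs:
                exceed += 1
            if stop_exceed > 0 and exceed >= stop_exceed:
                break
            if exceed < len(stop_m) and done <= stop_m[exceed]:
                break
            if min_accept > 0 and done >= min_accept and exceed == 0:
                break
        return done, exceed

    _perm_exceed_impl = _perm_exceed_numpy


@dataclass(frozen=True)
class SegmentationParams:
    alpha: float = 0.05
    n_perm: int = 1000
    min_width: int = 2
    undo_sd: float = 1.0  # 0 disables merge-undo
    seed: int = 0
    early_stop: bool = True  # sequential stopping of the permutation loop

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if self.undo_sd < 0:
            raise ValueError("undo_sd must be >= 0")


@dataclass(frozen=True)
class SegmentSet:
    """Genome-ordered constant-copy segments for one sample.

    ``table`` columns: chrom, start_bin, end_bin (global bin indices,
    half-open), start_bp, end_bp, n_bins (unmasked member bins),
    mean_value, mean_z, mean_ratio, sigma (standard error of mean_ratio),
    split_p.
    """

    sample_id: str
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def max_circular_t(x: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Best circular split of ``x``: boundaries (i, j) and max |t|.

    Returns ``(-1, -1, 0.0)`` when no admissible split exists (too short or
    constant input). Ties go to the smallest i, then smallest j; an arc and
    its complement are the same split, so the reported pair is the
    lexicographically first representative.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if len(x) < 2 * min_width:
        return _NO_SPLIT
    i, j, t = _max_t_impl(x, min_width)
    if i < 0 or t <= 0.0:
        return _NO_SPLIT
    return int(i), int(j), float(t)


def split_p_value(x: np.ndarray, t_obs: float,
                  params: SegmentationParams) -> float:
    """Permutation p-value for an observed max split statistic.

    p = (1 + #{T_perm >= T_obs}) / (1 + n_perm), with the full ``n_perm``
    permutations always run (no early stopping at this public entry point).
    A sentinel ``t_obs`` of -inf or <= 0 returns 1.
    """
    if math.isnan(t_obs) or t_obs <= 0.0:
        return 1.0
    x = np.ascontiguousarray(x, dtype=np.float64)
    done, exceed = _perm_exceed_impl(
        x, float(t_obs), params.n_perm, params.min_width, params.seed, 0, 0,
        _NO_STOP_TABLE,
    )
    return (1.0 + exceed) / (1.0 + done)


_NO_STOP_TABLE = np.zeros(1, dtype=np.int64)
_stop_table_cache: dict[tuple, np.ndarray] = {}


def _early_stop_table(alpha: float, n_perm: int, min_exceed: int = 10,
                      conf: float = 1e-3) -> np.ndarray:
    """Sequential stopping rule for the permutation loop.

    ``table[e]`` is the largest permutation count m at which e exceedances
    already prove (at confidence 1-conf, Clopper-Pearson lower bound) that
    the exceedance probability is above alpha, so the split can be declared
    non-significant without running the rest. 0 means never stop at e.
    """
    key = (alpha, n_perm, min_exceed, conf)
    cached = _stop_table_cache.get(key)
    if cached is not None:
        return cached
    from scipy.stats import beta

    stop_exceed = int(math.ceil(alpha * (1 + n_perm)))
    table = np.zeros(stop_exceed + 1, dtype=np.int64)
    for e in range(min_exceed, stop_exceed + 1):
        lo, hi = e, n_perm
        if beta.ppf(conf, e, lo - e + 1) <= alpha:
            continue
        while lo < hi:  # largest m with lower bound still above alpha
            mid = (lo + hi + 1) // 2
            if beta.ppf(conf, e, mid - e + 1) > alpha:
                lo = mid
            else:
                hi = mid - 1
        table[e] = lo
    _stop_table_cache[key] = table
    return table


def _split_test(x, params, seed, min_accept=100):
    """One split decision with optional sequential stopping.

    Early termination is exact once the exceedance count alone guarantees
    p >= alpha, statistically safe (error rate ~1e-3) via the
    Clopper-Pearson table above, and approximate on the accept side (stop
    at ``min_accept`` permutations with zero exceedances).
    """
    i, j, t = max_circular_t(x, params.min_width)
    if i < 0:
        return i, j, 1.0
    if params.early_stop:
        stop_exceed = int(math.ceil(params.alpha * (1 + params.n_perm)))
        accept = min(min_accept, params.n_perm)
        stop_m = _early_stop_table(params.alpha, params.n_perm)
    else:
        stop_exceed = 0
        accept = 0
        stop_m = _NO_STOP_TABLE
    done, exceed = _perm_exceed_impl(
        np.ascontiguousarray(x, dtype=np.float64),
        float(t), params.n_perm, params.min_width, seed, stop_exceed, accept,
        stop_m,
    )
    return i, j, (1.0 + exceed) / (1.0 + done)


def _segment_chrom(x: np.ndarray, params: SegmentationParams,
                   seed: int) -> list[tuple[int, int, float]]:
    """Recursive CBS of one chromosome's values.

    Returns (lo, hi, split_p) pieces covering [0, len(x)); split_p is the
    p-value of the split event that created the piece (NaN for a never-split
    chromosome root).
    """
    pieces: list[tuple[int, int, float]] = []
    counter = [0]

    def recurse(lo: int, hi: int, creation_p: float) -> None:
        n = hi - lo
        if n >= 2 * params.min_width:
            counter[0] += 1
            i, j, p = _split_test(x[lo:hi], params, seed + counter[0])
            if i >= 0 and p < params.alpha:
                cuts = sorted({c for c in (i, j) if 0 < c < n})
                edges = [lo] + [lo + c for c in cuts] + [hi]
                for a, b in zip(edges[:-1], edges[1:]):
                    recurse(a, b, p)
                return
        pieces.append((lo, hi, creation_p))

    recurse(0, len(x), float("nan"))
    pieces.sort()
    return pieces


def _undo_boundaries(x: np.ndarray, edges: list[int], undo_sd: float) -> list[int]:
    """Drop internal edges whose standardized mean change is below undo_sd.

    The change at a boundary is standardized by the standard error of the
    mean difference, sp * sqrt(1/n1 + 1/n2) with sp the pooled
    within-segment SD — scaling by the raw per-bin SD instead would erase
    every genuine low-tumor-fraction step (those are well under one bin-SD
    by construction). Iteratively removes the weakest boundary until all
    survivors exceed the threshold. ``edges`` includes 0 and len(x).
    """
    if undo_sd <= 0:
        return edges
    edges = list(edges)
    while len(edges) > 2:
        scores = []
        for k in range(1, len(edges) - 1):
            left = x[edges[k - 1]:edges[k]]
            right = x[edges[k]:edges[k + 1]]
            d = abs(left.mean() - right.mean())
            ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            dof = len(left) + len(right) - 2
            sp = math.sqrt(ss / dof) if dof > 0 else 0.0
            se = sp * math.sqrt(1.0 / len(left) + 1.0 / len(right))
            if se < _VAR_EPS:
                scores.append(0.0 if d < _VAR_EPS else float("inf"))
            else:
                scores.append(d / se)
        weakest = int(np.argmin(scores))
        if scores[weakest] >= undo_sd:
            break
        del edges[weakest + 1]
    return edges


def segment_values(values: np.ndarray, bins: GenomeBins,
                   params: SegmentationParams,
                   mask: np.ndarray | None = None,
                   aux: dict[str, np.ndarray] | None = None,
                   sample_id: str = "sample") -> SegmentSet:
    """Segment one per-bin statistic chromosome by chromosome.

    Masked (or NaN) bins are dropped before segmentation; segment bp spans
    use the surviving bins' coordinates. ``aux`` maps extra column names to
    per-bin vectors averaged within each segment (e.g. z values).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(bins):
        raise ValueError("values not aligned to bins")
    if mask is None:
        mask = np.isfinite(values)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    aux = aux or {}

    rows = []
    for ci, chrom in enumerate(bins.chroms):
        sl = bins.chrom_slice(chrom)
        cmask = mask[sl]
        if not cmask.any():
            continue
        local = np.flatnonzero(cmask) + sl.start  # global indices of used bins
        x = values[local]
        pieces = _segment_chrom(x, params, seed=params.seed + 100_003 * ci)
        edges = [p[0] for p in pieces] + [len(x)]
        pvals = {p[0]: p[2] for p in pieces}
        edges = _undo_boundaries(x, edges, params.undo_sd)
        starts_bp = bins.starts
        ends_bp = bins.ends
        for a, b in zip(edges[:-1], edges[1:]):
            seg_bins = local[a:b]
            seg_vals = x[a:b]
            n = len(seg_vals)
            mad = np.median(np.abs(seg_vals - np.median(seg_vals)))
            sigma = max(1.4826 * mad / math.sqrt(n), 1e-3)
            row = {
                "chrom": chrom,
                "start_bin": int(seg_bins[0]),
                "end_bin": int(seg_bins[-1]) + 1,
                "start_bp": int(starts_bp[seg_bins[0]]),
                "end_bp": int(ends_bp[seg_bins[-1]]),
                "n_bins": n,
                "mean_value": float(seg_vals.mean()),
                "sigma": float(sigma),
                "split_p": pvals.get(a, float("nan")),
            }
            for name, vec in aux.items():
                row[name] = float(np.nanmean(np.asarray(vec, dtype=float)[seg_bins]))
            rows.append(row)
    table = pd.DataFrame(rows)
    return SegmentSet(sample_id=sample_id, table=table)


def segment_profile(zp: ZProfile, bins: GenomeBins,
                    params: SegmentationParams,
                    statistic: str = "ratio") -> SegmentSet:
    """Segment a Z-profile on its log2 ratio (default) or z statistic.

    Both per-segment mean z and mean ratio are reported regardless of which
    statistic drove the segmentation.
    """
    if statistic not in ("ratio", "z"):
        raise ValueError("statistic must be 'ratio' or 'z'")
    primary = zp.ratio if statistic == "ratio" else zp.z
    segset = segment_values(
        primary, bins, params, mask=zp.mask,
        aux={"mean_z": zp.z},
        sample_id=zp.sample_id,
    )
    # Segment-level log ratio is log2 of the mean linear ratio, not the mean
    # of per-bin logs: the latter carries a noise-dependent (Jensen) offset
    # of several standard errors on chromosome-sized segments.
    t = segset.table
    linear = np.power(2.0, zp.ratio)
    mean_ratio = np.empty(len(t))
    sigma = np.empty(len(t))
    for k, row in enumerate(t.itertuples()):
        vals = linear[row.start_bin:row.end_bin]
        vals = vals[np.isfinite(vals)]
        m = vals.mean()
        mean_ratio[k] = math.log2(max(m, 1e-6))
        mad = np.median(np.abs(vals - np.median(vals)))
        se_lin = 1.4826 * mad / math.sqrt(len(vals))
        sigma[k] = max(se_lin / (max(m, 1e-6) * math.log(2.0)), 1e-3)
    t = t.assign(mean_ratio=mean_ratio, sigma=sigma)
    return SegmentSet(sample_id=segset.sample_id, table=t)


def merge_undo(segments: SegmentSet, values: np.ndarray, bins: GenomeBins,
               undo_sd: float) -> SegmentSet:
    """Re-apply the undo rule to an existing segment set.

    ``values`` is the full per-bin vector the segments were built from
    (NaN on masked bins); means are recomputed after merging.
    """
    values = np.asarray(values, dtype=float)
    t = segments.table
    rows = []
    for chrom, grp in t.groupby("chrom", sort=False):
        grp = grp.sort_values("start_bin")
        used = np.concatenate([
            np.arange(r.start_bin, r.end_bin)[
                np.isfinite(values[r.start_bin:r.end_bin])
            ]
            for r in grp.itertuples()
        ])
        x = values[used]
        # translate segment bounds into positions within the unmasked vector
        edges = [0]
        for r in grp.itertuples():
            n = int(np.isfinite(values[r.start_bin:r.end_bin]).sum())
            edges.append(edges[-1] + n)
        edges = _undo_boundaries(x, edges, undo_sd)
        for a, b in zip(edges[:-1], edges[1:]):
            seg_bins = used[a:b]
            seg_vals = x[a:b]
            mad = np.median(np.abs(seg_vals - np.median(seg_vals)))
            rows.append({
                "chrom": chrom,
                "start_bin": int(seg_bins[0]),
                "end_bin": int(seg_bins[-1]) + 1,
                "start_bp": int(bins.starts[seg_bins[0]]),
                "end_bp": int(bins.ends[seg_bins[-1]]),
                "n_bins": len(seg_vals),
                "mean_value": float(seg_vals.mean()),
                "sigma": max(
                    1.4826 * float(np.median(np.abs(seg_vals - np.median(seg_vals))))
                    / math.sqrt(len(seg_vals)),
                    1e-3,
                ),
                "split_p": float("nan"),
                "mean_z": float("nan"),
                "mean_ratio": float(seg_vals.mean()),
            })
    return SegmentSet(sample_id=segments.sample_id, table=pd.DataFrame(rows))


def write_seg(segments: SegmentSet, path) -> None:
    """Write a SEG file (1-based inclusive coordinates, segment mean ratio)."""
    t = segments.table
    out = pd.DataFrame({
        "ID": segments.sample_id,
        "chrom": t["chrom"],
        "loc.start": t["start_bp"] + 1,
        "loc.end": t["end_bp"],
        "num.mark": t["n_bins"],
        "seg.mean": t.get("mean_ratio", t["mean_value"]).round(6),
    })
    out.to_csv(path, sep="\t", index=False)


def write_segments_tsv(segments: SegmentSet, path) -> None:
    t = segments.table.copy()
    t.insert(0, "sample_id", segments.sample_id)
    t.to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> SegmentSet:
    t = pd.read_csv(path, sep="\t")
    sid = str(t["sample_id"].iloc[0]) if "sample_id" in t.columns and len(t) else "sample"
    return SegmentSet(sample_id=sid, table=t.drop(columns=["sample_id"], errors="ignore"))
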