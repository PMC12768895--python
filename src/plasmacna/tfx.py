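"""Tumor DNA fraction (TFx) estimation from segment-level CNA burden.

A two-component mixture: a fraction f of the cfDNA carries integer copy
state c, the remainder is diploid, so a segment with tumor copy state c is
expected at log2 ratio

    log2((f*c + 2*(1 - f)) / 2)

Estimation is a grid search over f; at each candidate f every segment is
assigned the copy state maximizing a Gaussian log-likelihood of its mean
ratio around the expected value, minus a per-segment penalty for any
non-diploid call. The penalty is calibrated so that flat noisy genomes
land on f = 0 (the maximum noise z across ~20-40 null segments must not
buy a spurious state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .segment import SegmentSet

LOG2_FLOOR = -10.0  # log ratio assigned to total loss at f=1
DETECTABLE_TFX = 0.002  # reporting threshold: 0.2%

__all__ = [
    "TFxModelParams",
    "TumorFractionEstimate",
    "expected_logratio",
    "estimate_tfx",
    "classify_detectable",
]


def _default_grid() -> np.ndarray:
    lo = np.arange(0.0, 0.6, 0.0025)
    hi = np.arange(0.6, 1.0 + 1e-9, 0.01)
    return np.unique(np.clip(np.concatenate([lo, hi]), 0.0, 1.0))


@dataclass(frozen=True)
class TFxModelParams:
    f_grid: np.ndarray = field(default_factory=_default_grid)
    # c=0 deliberately absent: an arm-scale homozygous deletion is not a
    # plausible cfDNA signal, and allowing it restores the exact {3,1}@f ==
    # {4,0}@f/2 degeneracy that the distance penalty is meant to break.
    states: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 12)
    non_diploid_penalty: float = 6.0
    state_distance_penalty: float = 1.0  # extra cost per copy step from diploid
    sigma_floor: float = 1e-3
    min_fit_bins: int = 25  # short segments are excluded from the f search

    def __post_init__(self) -> None:
        grid = np.asarray(self.f_grid, dtype=float)
        if (grid < 0).any() or (grid > 1).any():
            raise ValueError("f_grid must lie in [0, 1]")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("f_grid must be strictly increasing")
        if 2 not in self.states:
            raise ValueError("states must include the diploid state 2")
        if self.non_diploid_penalty < 0:
            raise ValueError("non_diploid_penalty must be >= 0")
        object.__setattr__(self, "f_grid", grid)


@dataclass(frozen=True)
class TumorFractionEstimate:
    sample_id: str
    tfx: float
    states: np.ndarray  # per-segment assigned copy state, segment order
    log_likelihood: float
    detectable: bool

    @property
    def tfx_percent(self) -> float:
        return 100.0 * self.tfx


def expected_logratio(c: int, f: float) -> float:
    """Expected log2 coverage ratio of a segment at copy state c, fraction f."""
    if c < 0:
        raise ValueError("copy state must be >= 0")
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rel = (f * c + 2.0 * (1.0 - f)) / 2.0
    if rel <= 0.0:
        return LOG2_FLOOR
    return max(math.log2(rel), LOG2_FLOOR)


def _score_at_f(ratios, sigmas, weights, f, states, penalty, gamma):
    """(total score, state assignment) at one candidate fraction.

    Two passes: the first assignment fixes the genome-average expected
    coverage (depth normalization couples segments: observed ratios are
    relative to the sample mean, not to pure diploid), the second assigns
    states against the re-centered expectations.

    ``gamma`` grows the penalty with |c - 2|, breaking the exact
    degeneracy between states {3,1} at fraction f and {4,0} at f/2.
    """
    mu = np.array([expected_logratio(c, f) for c in states])
    states_arr = np.array(states, dtype=float)
    pen = np.where(states_arr == 2.0, 0.0,
                   penalty + gamma * np.abs(states_arr - 2.0))

    assign = np.argmin(
        (ratios[:, None] - mu[None, :]) ** 2 / (2.0 * sigmas[:, None] ** 2)
        + pen[None, :],
        axis=1,
    )
    # recenter: mean relative coverage of the implied genome
    rel = (f * states_arr[assign] + 2.0 * (1.0 - f)) / 2.0
    mbar = float(np.average(rel, weights=weights))
    mu_centered = mu - math.log2(max(mbar, 1e-6))

    cost = (
        (ratios[:, None] - mu_centered[None, :]) ** 2 / (2.0 * sigmas[:, None] ** 2)
        + pen[None, :]
    )
    assign = np.argmin(cost, axis=1)
    score = -float(cost[np.arange(len(ratios)), assign].sum())
    return score, assign


def estimate_tfx(segments: SegmentSet,
                 params: TFxModelParams | None = None) -> TumorFractionEstimate:
    """Grid-search the tumor fraction maximizing the segment likelihood.

    Ties resolve toward the smallest f (prefer less tumor). Deterministic;
    invariant to segment order.
    """
    params = params or TFxModelParams()
    t = segments.table
    if len(t) == 0:
        raise ValueError("cannot estimate TFx from an empty segment set")
    ratios = t["mean_ratio"].to_numpy(dtype=float) if "mean_ratio" in t.columns \
        else t["mean_value"].to_numpy(dtype=float)
    if not np.isfinite(ratios).all():
        raise ValueError("segment mean ratios must be finite")
    sigmas = np.maximum(
        t["sigma"].to_numpy(dtype=float) if "sigma" in t.columns
        else np.full(len(t), 0.05),
        params.sigma_floor,
    )
    weights = t["n_bins"].to_numpy(dtype=float)

    # Only segments of meaningful genomic span inform the fraction: a short
    # spurious segment (CBS admits ~alpha false splits per chromosome) can
    # otherwise buy an arbitrary likelihood gain at an absurd f.
    fit = weights >= params.min_fit_bins
    if not fit.any():
        states = np.full(len(t), 2, dtype=int)
        return TumorFractionEstimate(
            sample_id=segments.sample_id, tfx=0.0, states=states,
            log_likelihood=0.0, detectable=False,
        )
    best_f, best_score = 0.0, -np.inf
    for f in params.f_grid:
        score, _ = _score_at_f(
            ratios[fit], sigmas[fit], weights[fit], float(f), params.states,
            params.non_diploid_penalty, params.state_distance_penalty,
        )
        if score > best_score + 1e-12:  # strict improvement: ties keep smaller f
            best_f, best_score = float(f), score
    _, assign_all = _score_at_f(
        ratios, sigmas, weights, best_f, params.states,
        params.non_diploid_penalty, params.state_distance_penalty,
    )
    states = np.array([params.states[a] for a in assign_all], dtype=int)
    return TumorFractionEstimate(
        sample_id=segments.sample_id,
        tfx=best_f,
        states=states,
        log_likelihood=best_score,
        detectable=best_f >= DETECTABLE_TFX,
    )


def classify_detectable(est: TumorFractionEstimate,
                        threshold: float = DETECTABLE_TFX) -> bool:
    """True when the estimated fraction reaches the reporting threshold."""
    return est.tfx >= threshold
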