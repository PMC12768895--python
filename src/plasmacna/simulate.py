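"""Synthetic low-pass WGS cfDNA cohort generator.

Bin counts follow a negative-binomial mixture: the expected count in bin b
of a sample with tumor fraction f and true copy state c_b is

    lambda_b = depth * bias_b * (f * c_b + 2 * (1 - f)) / 2

where ``bias_b`` is a per-bin systematic factor shared by every sample of a
cohort (it is what the control baseline removes). The dispersion parameter
is the negative-binomial size r, giving variance lambda * (1 + lambda / r).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .genome import GenomeBins

DEFAULT_DEPTH = 60.0  # expected read pairs per 200-kb bin (~19.5M pairs genome-wide)
DEFAULT_DISPERSION = 120.0  # variance ~ 1.5x mean at depth 60
DEFAULT_BIAS_SD = 0.1

PRESET_NAMES = ("flat", "nb_17q_1p", "nb_11q", "nb_mycn_amp", "hyperdiploid", "gn_like")

__all__ = [
    "CNAEvent",
    "SimSampleSpec",
    "SimTruth",
    "preset_events",
    "draw_bias",
    "simulate_sample",
    "simulate_cohort",
    "demo_cohort_specs",
]


@dataclass(frozen=True)
class CNAEvent:
    """One constant-copy event on a simulated genome (c=2 is diploid)."""

    chrom: str
    start: int
    end: int
    copy_state: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"event start must be < end: {self}")
        if self.copy_state < 0:
            raise ValueError(f"copy_state must be >= 0: {self}")


@dataclass(frozen=True)
class SimSampleSpec:
    sample_id: str
    tumor_fraction: float = 0.0
    events: tuple[CNAEvent, ...] | str = ()
    depth: float = DEFAULT_DEPTH
    dispersion: float = DEFAULT_DISPERSION
    seed: int = 0
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def resolved_events(self) -> tuple[CNAEvent, ...]:
        if isinstance(self.events, str):
            return tuple(preset_events(self.events))
        return tuple(self.events)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    copy_state: np.ndarray  # per-bin integer copy state
    tumor_fraction: float
    boundaries: tuple[int, ...]  # bin indices where copy state changes
    events: tuple[CNAEvent, ...]

    @property
    def n_events(self) -> int:
        return len(self.events)


def _arm_span(chrom: str, arm: str) -> tuple[int, int]:
    # Coordinates from the bundled hg19-like karyotype.
    from .genome import load_default_karyotype

    kt = load_default_karyotype(include_sex=True)
    length = kt.length_of(chrom)
    cen = kt.centromere_of(chrom)
    return (0, cen) if arm == "p" else (cen, length)


def preset_events(name: str) -> list[CNAEvent]:
    """Fixed event lists for recurrent neuroblastic-tumor profiles.

    ``nb_*`` presets combine the recurrent arm gains (17q, 7, 2p, 1q) and
    losses (1p, 3p, 11q, 14q); ``nb_mycn_amp`` adds a focal ~1-Mb chr2p
    amplification; ``hyperdiploid`` is whole-chromosome trisomies; ``flat``
    and ``gn_like`` are copy-neutral.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if name in ("flat", "gn_like"):
        return []
    if name == "nb_17q_1p":
        return [
            CNAEvent("chr17", *_arm_span("chr17", "q"), 3),
            CNAEvent("chr1", *_arm_span("chr1", "p"), 1),
            CNAEvent("chr7", 0, 159_138_663, 3),
            CNAEvent("chr11", *_arm_span("chr11", "q"), 1),
        ]
    if name == "nb_11q":
        return [
            CNAEvent("chr11", *_arm_span("chr11", "q"), 1),
            CNAEvent("chr17", *_arm_span("chr17", "q"), 3),
            CNAEvent("chr3", *_arm_span("chr3", "p"), 1),
            CNAEvent("chr14", *_arm_span("chr14", "q"), 1),
        ]
    if name == "nb_mycn_amp":
        return [
            CNAEvent("chr2", 15_500_000, 16_500_000, 15),  # focal amplification
            CNAEvent("chr17", *_arm_span("chr17", "q"), 3),
            CNAEvent("chr1", *_arm_span("chr1", "p"), 1),
        ]
    if name == "hyperdiploid":
        return [
            CNAEvent("chr2", 0, 243_199_373, 3),
            CNAEvent("chr7", 0, 159_138_663, 3),
            CNAEvent("chr12", 0, 133_851_895, 3),
            CNAEvent("chr13", 0, 115_169_878, 3),
            CNAEvent("chr17", 0, 81_195_210, 3),
        ]
    raise AssertionError("unreachable")


def copy_state_vector(events, bins: GenomeBins) -> np.ndarray:
    """Per-bin true copy state; a bin takes an event's state if its midpoint
    falls inside the event. Overlapping events: later in the sorted list wins
    (sort by chrom, start, end — deterministic last-writer-wins).
    """
    c = np.full(len(bins), 2, dtype=np.int64)
    t = bins.table
    mid = (t["start"].to_numpy() + t["end"].to_numpy()) // 2
    chroms = t["chrom"].to_numpy()
    for ev in sorted(events, key=lambda e: (e.chrom, e.start, e.end)):
        sel = (chroms == ev.chrom) & (mid >= ev.start) & (mid < ev.end)
        c[sel] = ev.copy_state
    return c


def draw_bias(n_bins: int, bias_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Lognormal per-bin bias factors shared across a cohort."""
    if bias_sd < 0:
        raise ValueError("bias_sd must be >= 0")
    if bias_sd == 0:
        return np.ones(n_bins)
    return np.exp(rng.normal(0.0, bias_sd, size=n_bins))


def expected_counts(
    spec: SimSampleSpec, bins: GenomeBins, bias: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(lambda_b, c_b) for the spec's mixture; no noise applied."""
    if len(bias) != len(bins):
        raise ValueError(f"bias length {len(bias)} != bin count {len(bins)}")
    c = copy_state_vector(spec.resolved_events(), bins)
    f = spec.tumor_fraction
    lam = spec.depth * bias * (f * c + 2.0 * (1.0 - f)) / 2.0
    return lam, c


def simulate_sample(
    spec: SimSampleSpec, bins: GenomeBins, bias: np.ndarray
) -> tuple[CoverageProfile, SimTruth]:
    """Draw one sample's bin counts; deterministic under ``spec.seed``."""
    lam, c = expected_counts(spec, bins, bias)
    rng = np.random.default_rng(spec.seed)
    r = spec.dispersion
    p = r / (r + lam)
    raw = rng.negative_binomial(r, p).astype(np.int64)
    profile = CoverageProfile(
        sample_id=spec.sample_id, raw=raw, n_reads_total=int(raw.sum())
    )
    changes = np.flatnonzero(np.diff(c)) + 1
    truth = SimTruth(
        sample_id=spec.sample_id,
        copy_state=c,
        tumor_fraction=spec.tumor_fraction,
        boundaries=tuple(int(b) for b in changes),
        events=spec.resolved_events(),
    )
    return profile, truth


def simulate_cohort(
    specs: list[SimSampleSpec],
    n_controls: int,
    bins: GenomeBins,
    seed: int = 0,
    bias_sd: float = DEFAULT_BIAS_SD,
    depth: float = DEFAULT_DEPTH,
    dispersion: float = DEFAULT_DISPERSION,
):
    """Simulate a full cohort sharing one bias vector.

    Returns ``(profiles, sample_sheet, truths)``: dict of CoverageProfile by
    sample_id, a sample-sheet DataFrame, and dict of SimTruth. Controls are
    flat (f=0); every sample's noise seed derives from ``seed``.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 controls to form a baseline SD")
    ss = np.random.SeedSequence(seed)
    bias_seed, *sample_seeds = ss.spawn(1 + n_controls + len(specs))
    bias = draw_bias(len(bins), bias_sd, np.random.default_rng(bias_seed))

    all_specs: list[SimSampleSpec] = []
    for i in range(n_controls):
        all_specs.append(
            SimSampleSpec(
                sample_id=f"control_{i + 1:02d}",
                tumor_fraction=0.0,
                events=(),
                depth=depth,
                dispersion=dispersion,
                labels={"histology": "HC", "group": "control", "timepoint": "NA"},
            )
        )
    all_specs.extend(specs)

    profiles, truths, rows = {}, {}, []
    for spec, sseed in zip(all_specs, sample_seeds):
        spec = replace(spec, seed=int(sseed.generate_state(1)[0]))
        prof, truth = simulate_sample(spec, bins, bias)
        profiles[spec.sample_id] = prof
        truths[spec.sample_id] = truth
        row = {
            "sample_id": spec.sample_id,
            "true_tfx": spec.tumor_fraction,
            "depth": spec.depth,
        }
        row.update(spec.labels)
        rows.append(row)
    sheet = pd.DataFrame(rows)
    return profiles, sheet, truths


def demo_cohort_specs(
    n_pairs: int = 0,
    depth: float = DEFAULT_DEPTH,
    fold_reduction: float = 50.0,
) -> list[SimSampleSpec]:
    """Mixed-preset tumor specs mirroring a small neuroblastic-tumor cohort.

    Optionally appends ``n_pairs`` pre/post-chemotherapy pairs whose post
    sample reuses the pre event set at ``tumor_fraction / fold_reduction``.
    """
    base = [
        ("nb_a", "nb_17q_1p", 0.10, {"histology": "NB", "risk": "high"}),
        ("nb_b", "nb_17q_1p", 0.20, {"histology": "NB", "risk": "high"}),
        ("nb_c", "nb_17q_1p", 0.40, {"histology": "NB", "risk": "high"}),
        ("nb_d", "nb_11q", 0.15, {"histology": "NB", "risk": "intermediate"}),
        ("nb_e", "nb_mycn_amp", 0.25, {"histology": "NB", "risk": "high", "mycn": "amp"}),
        ("nb_f", "hyperdiploid", 0.30, {"histology": "NB", "risk": "low"}),
        ("gnb_a", "nb_11q", 0.002, {"histology": "GNB", "risk": "low"}),
        ("gn_a", "gn_like", 0.0, {"histology": "GN", "risk": "low"}),
    ]
    specs = [
        SimSampleSpec(
            sample_id=sid,
            tumor_fraction=f,
            events=preset,
            depth=depth,
            labels={**labels, "group": "tumor", "timepoint": "diagnosis"},
        )
        for sid, preset, f, labels in base
    ]
    rng = np.random.default_rng(20_240_601)
    for i in range(n_pairs):
        f_pre = float(rng.uniform(0.10, 0.48))
        preset = ["nb_17q_1p", "nb_11q", "nb_mycn_amp"][i % 3]
        pair = f"pair_{i + 1:02d}"
        specs.append(
            SimSampleSpec(
                sample_id=f"{pair}_pre",
                tumor_fraction=f_pre,
                events=preset,
                depth=depth,
                labels={"histology": "NB", "group": "paired", "timepoint": "pre",
                        "pair_id": pair},
            )
        )
        specs.append(
            SimSampleSpec(
                sample_id=f"{pair}_post",
                tumor_fraction=f_pre / fold_reduction,
                events=preset,
                depth=depth,
                labels={"histology": "NB", "group": "paired", "timepoint": "post",
                        "pair_id": pair},
            )
        )
    return specs
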