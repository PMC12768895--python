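"""End-to-end orchestration: simulate/load -> normalize -> segment -> TFx
-> HRD -> arm calls -> decision flags, with a reproducible run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage, diagnostics, scars, segment, simulate, tfx
from .genome import Karyotype, load_default_karyotype, make_bins

log = logging.getLogger("plasmacna")

__all__ = ["RunConfig", "ValidationError", "run_pipeline", "decision_flags"]


class ValidationError(ValueError):
    """Configuration or input problem detected before any compute."""


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    karyotype: str = "default"  # path to TSV or "default"
    bin_size: int = 200_000
    controls: list = field(default_factory=list)  # count TSV paths
    samples: list = field(default_factory=list)  # count TSV paths
    simulate: dict | None = None  # {"preset_cohort": "demo", "n_controls": 11, ...}
    alpha: float = 0.05
    n_perm: int = 1000
    min_width: int = 2
    undo_sd: float = 1.0
    non_diploid_penalty: float = 6.0
    tfx_threshold: float = 0.002
    z_threshold: float = 3.0
    lga_min_size: int = 10_000_000
    lga_delta_min: float = 0.1
    flag_rule: str = "and"  # both conditions required for follow-up
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate is None:
            if len(self.controls) < 2:
                raise ValidationError("need >= 2 control count files (or a simulate block)")
            for path in list(self.controls) + list(self.samples):
                if not Path(path).exists():
                    raise ValidationError(f"input file missing: {path}")
        if self.karyotype != "default" and not Path(self.karyotype).exists():
            raise ValidationError(f"karyotype file missing: {self.karyotype}")
        if self.flag_rule not in ("and", "or"):
            raise ValidationError("flag_rule must be 'and' or 'or'")
        segment.SegmentationParams(  # reuses the stage validators
            alpha=self.alpha, n_perm=self.n_perm, min_width=self.min_width,
            undo_sd=self.undo_sd, seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def decision_flags(results: pd.DataFrame, tfx_threshold: float = 0.002,
                   z_threshold: float = 3.0, rule: str = "and") -> pd.DataFrame:
    """Per-sample follow-up / discontinue flags.

    Follow-up: TFx >= threshold AND at least one arm with |aggregate Z| >=
    z_threshold (the conjunction is switchable to OR). Discontinue-style
    negative: TFx below threshold AND every arm |Z| below z_threshold.
    Expects columns ``tfx`` and ``max_abs_arm_z``.
    """
    high_tfx = results["tfx"] >= tfx_threshold
    aberrant = results["max_abs_arm_z"] >= z_threshold
    if rule == "and":
        followup = high_tfx & aberrant
    elif rule == "or":
        followup = high_tfx | aberrant
    else:
        raise ValueError("rule must be 'and' or 'or'")
    out = results.copy()
    out["flag_followup"] = followup
    out["flag_negative"] = (~high_tfx) & (~aberrant)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig, bins):
    """Returns (control profiles, sample profiles, sample sheet, truths)."""
    if config.simulate is not None:
        sim = dict(config.simulate)
        n_controls = int(sim.get("n_controls", 11))
        depth = float(sim.get("depth", simulate.DEFAULT_DEPTH))
        bias_sd = float(sim.get("bias_sd", simulate.DEFAULT_BIAS_SD))
        if sim.get("preset_cohort", "demo") == "demo":
            specs = simulate.demo_cohort_specs(
                n_pairs=int(sim.get("n_pairs", 0)), depth=depth,
            )
        else:
            raise ValidationError(
                f"unknown preset_cohort {sim.get('preset_cohort')!r}"
            )
        profiles, sheet, truths = simulate.simulate_cohort(
            specs, n_controls, bins, seed=config.seed,
            bias_sd=bias_sd, depth=depth,
        )
        controls = [profiles[s] for s in sheet.loc[sheet["group"] == "control",
                                                   "sample_id"]]
        tumors = [profiles[s] for s in sheet.loc[sheet["group"] != "control",
                                                 "sample_id"]]
        return controls, tumors, sheet, truths
    controls = [coverage.read_counts_tsv(p, bins, sample_id=Path(p).stem)
                for p in config.controls]
    samples = [coverage.read_counts_tsv(p, bins, sample_id=Path(p).stem)
               for p in config.samples]
    sheet = pd.DataFrame({"sample_id": [c.sample_id for c in controls + samples],
                          "group": ["control"] * len(controls)
                                   + ["sample"] * len(samples)})
    return controls, samples, sheet, {}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg_dir = out_dir / "segments"
    seg_dir.mkdir(exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {"stages": [], "seed": config.seed, "inputs": {}}
    for path in list(config.controls) + list(config.samples):
        manifest["inputs"][str(path)] = _sha256(Path(path))

    kt = (load_default_karyotype() if config.karyotype == "default"
          else Karyotype.from_tsv(config.karyotype))
    bins = make_bins(kt, config.bin_size)
    manifest["n_bins"] = len(bins)
    bins.to_bed(out_dir / "bins.bed")

    controls, samples, sheet, truths = _load_inputs(config, bins)
    sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
    manifest["stages"].append({"name": "load", "n_controls": len(controls),
                               "n_samples": len(samples)})

    controls = [coverage.depth_normalize(c) for c in controls]
    baseline = coverage.build_baseline(controls)
    baseline.to_frame(bins).to_csv(out_dir / "baseline.tsv", sep="\t", index=False)
    manifest["stages"].append({"name": "baseline",
                               "usable_bins": int(baseline.mask.sum())})

    seg_params = segment.SegmentationParams(
        alpha=config.alpha, n_perm=config.n_perm, min_width=config.min_width,
        undo_sd=config.undo_sd, seed=config.seed,
    )
    tfx_params = tfx.TFxModelParams(non_diploid_penalty=config.non_diploid_penalty)

    rows = []
    # Controls are scored too (the TFx-vs-labels evaluation needs them);
    # note they are members of the baseline they are scored against.
    for prof in controls + samples:
        prof = coverage.depth_normalize(prof)
        zp = coverage.zscore(prof, baseline)
        segs = segment.segment_profile(zp, bins, seg_params)
        segment.write_seg(segs, seg_dir / f"{prof.sample_id}.seg")
        segment.write_segments_tsv(segs, seg_dir / f"{prof.sample_id}.segments.tsv")
        est = tfx.estimate_tfx(segs, tfx_params)
        scar = scars.lga_count(segs, kt, min_size=config.lga_min_size,
                               delta_min=config.lga_delta_min)
        calls = diagnostics.arm_calls(zp, bins, z_threshold=config.z_threshold)
        finite = [c.aggregate_z for c in calls if np.isfinite(c.aggregate_z)]
        max_abs_z = float(np.max(np.abs(finite))) if finite else 0.0
        rows.append({
            "sample_id": prof.sample_id,
            "tfx": est.tfx,
            "tfx_percent": est.tfx_percent,
            "detectable": est.detectable,
            "n_segments": len(segs),
            "lga_count": scar.lga_count,
            "max_abs_arm_z": max_abs_z,
            "n_arm_aberrations": sum(c.direction != "none" for c in calls),
        })
        log.info("sample %s: tfx=%.4f lga=%d max|Z|=%.2f",
                 prof.sample_id, est.tfx, scar.lga_count, max_abs_z)
    results = pd.DataFrame(rows)
    results = decision_flags(results, tfx_threshold=config.tfx_threshold,
                             z_threshold=config.z_threshold, rule=config.flag_rule)
    results = results.merge(sheet, on="sample_id", how="left")
    results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    manifest["stages"].append({"name": "per_sample", "n": len(results)})
    manifest["results_digest"] = hashlib.sha256(
        results.to_csv(index=False).encode()
    ).hexdigest()

    config.to_yaml(out_dir / "config.yaml")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
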