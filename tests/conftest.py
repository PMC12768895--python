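import numpy as np
import pandas as pd
import pytest

from plasmacna import coverage, genome, simulate


@pytest.fixture(scope="session")
def default_karyotype():
    return genome.load_default_karyotype()


@pytest.fixture(scope="session")
def reduced_karyotype(default_karyotype):
    """Event chromosomes plus diploid ballast — cheap stand-in for hg19."""
    keep = ["chr1", "chr2", "chr3", "chr7", "chr11", "chr14", "chr17", "chr22"]
    t = default_karyotype.table
    return genome.Karyotype(t[t["chrom"].isin(keep)].reset_index(drop=True))


@pytest.fixture(scope="session")
def small_bins():
    """Two toy chromosomes, 250 bins total."""
    kt = genome.Karyotype(pd.DataFrame({
        "chrom": ["c1", "c2"],
        "length": [30_000_000, 20_000_000],
        "centromere_mid": [10_000_000, 8_000_000],
    }))
    return kt, genome.make_bins(kt, 200_000)


@pytest.fixture(scope="session")
def loo_cohort():
    """11 flat controls on a 1,000-bin frame (leave-one-out calibration)."""
    kt = genome.Karyotype(pd.DataFrame({
        "chrom": ["c1"], "length": [200_000_000],
        "centromere_mid": [100_000_000],
    }))
    bins = genome.make_bins(kt, 200_000)
    rng = np.random.default_rng(7)
    bias = simulate.draw_bias(len(bins), 0.1, rng)
    controls = []
    for i in range(11):
        spec = simulate.SimSampleSpec(sample_id=f"ctrl{i}", seed=800 + i)
        prof, _ = simulate.simulate_sample(spec, bins, bias)
        controls.append(coverage.depth_normalize(prof))
    return bins, controls


@pytest.fixture(scope="session")
def small_cohort(small_bins):
    """11 flat controls on the small frame, shared bias, plus the baseline."""
    _, bins = small_bins
    rng = np.random.default_rng(42)
    bias = simulate.draw_bias(len(bins), 0.1, rng)
    controls = []
    for i in range(11):
        spec = simulate.SimSampleSpec(sample_id=f"ctrl{i}", seed=500 + i)
        prof, _ = simulate.simulate_sample(spec, bins, bias)
        controls.append(coverage.depth_normalize(prof))
    baseline = coverage.build_baseline(controls)
    return bins, bias, controls, baseline
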