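import numpy as np
import pandas as pd
import pytest

from methclass import (
    SimulationConfig,
    ClassSpec,
    CNVEvent,
    IntensityMatrix,
    generate_manifest,
    simulate_cohort,
)


def make_manifest(probe_ids, chroms=None, positions=None, strata=None, **flag_overrides):
    """Hand-built manifest with all-zero flags unless overridden."""
    n = len(probe_ids)
    df = pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "chrom": chroms if chroms is not None else ["chr1"] * n,
            "pos": positions if positions is not None else np.arange(1, n + 1) * 100,
            "stratum": strata if strata is not None else ["II"] * n,
            "in_450k": 1,
            "in_850k": 1,
            "flag_sex": 0,
            "flag_snp": 0,
            "flag_crossreactive": 0,
            "flag_nonunique": 0,
        }
    )
    for flag, ids in flag_overrides.items():
        df.loc[df["probe_id"].isin(ids), flag] = 1
    return df


def make_matrix(probe_ids, sample_values: dict):
    """IntensityMatrix from {sample: (meth_vector, unmeth_vector)}."""
    idx = pd.Index(list(probe_ids))
    meth = pd.DataFrame({s: np.asarray(v[0], float) for s, v in sample_values.items()}, index=idx)
    unmeth = pd.DataFrame({s: np.asarray(v[1], float) for s, v in sample_values.items()}, index=idx)
    return IntensityMatrix(meth, unmeth)


def flat_classes(n_classes, n_samples, n_sig=0, shift=0.0, labeled=True):
    return tuple(
        ClassSpec(f"C{k}", n_samples, n_sig, shift, (), 0.7, labeled)
        for k in range(n_classes)
    )


def simple_config(**kwargs):
    defaults = dict(
        n_probes_per_array=2000,
        overlap_fraction=1.0,
        n_chromosomes=4,
        chrom_length=30_000_000,
        classes=flat_classes(2, 5),
        n_reference_samples=4,
        beta_noise_sd=0.3,
        baseline_intensity=5000.0,
        intensity_dispersion=0.15,
        seed=0,
        flag_fractions=(0.0, 0.0, 0.0, 0.0),
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with one planted gain, shared across tests."""
    event = CNVEvent("chr1", 1, 15_000_000, "gain", 0.4, 1.0)
    config = simple_config(
        classes=(
            ClassSpec("flat", 6, 200, 0.4, (), 0.7, True),
            ClassSpec("cnv", 6, 200, 0.4, (event,), 0.4, False),
        ),
        n_reference_samples=5,
        seed=11,
    )
    manifest = generate_manifest(config)
    matrix, sheet, truth = simulate_cohort(config, manifest)
    return config, manifest, matrix, sheet, truth
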