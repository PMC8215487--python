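import numpy as np
import pandas as pd
import pytest

from evrppa import synthetic_data as sd


@pytest.fixture
def small_layout():
    return sd.AssayLayout(
        antibodies=("EpCAM", "PD-L1"),
        samples=("HD_01", "HD_02", "HD_03", "PCa_01", "PCa_02", "PCa_03"),
        replicates_per_spot=3,
        print_concentrations=(0.5, 0.125),
    )


@pytest.fixture
def small_cohort():
    return sd.CohortSpec(
        groups={"HD": 3, "PCa": 3},
        effects={("EpCAM", "PCa"): 2.0},
        noise_cv=0.0,
        loading_cv=0.0,
        baseline_intensity=100.0,
        assay_background=10.0,
        local_background=5.0,
        seed=0,
    )


@pytest.fixture
def noiseless_spots(small_layout, small_cohort):
    return sd.generate_slide(small_layout, small_cohort)


def random_spot_table(rng: np.random.Generator, n_samples=4, n_antibodies=3, n_rep=3):
    """Randomized but well-formed spot table for property tests."""
    layout = sd.AssayLayout(
        antibodies=tuple(f"AB{i}" for i in range(n_antibodies)),
        samples=tuple(f"S{i}" for i in range(n_samples)),
        replicates_per_spot=n_rep,
    )
    cohort = sd.CohortSpec(
        groups={"G": n_samples},
        noise_cv=float(rng.uniform(0.05, 0.3)),
        loading_cv=float(rng.uniform(0.0, 0.3)),
        baseline_intensity=float(rng.uniform(100, 2000)),
        assay_background=float(rng.uniform(5, 100)),
        local_background=float(rng.uniform(0, 50)),
        seed=int(rng.integers(0, 2**31)),
    )
    layout = sd.AssayLayout(
        antibodies=layout.antibodies,
        samples=tuple(s for s, _ in cohort.sample_ids()),
        replicates_per_spot=n_rep,
    )
    return sd.generate_slide(layout, cohort)


@pytest.fixture
def null_matrix():
    """40 samples x 200 endpoints with no group effect, plus annotation."""
    rng = np.random.default_rng(5)
    idx = [f"A_{i}" for i in range(20)] + [f"B_{i}" for i in range(20)]
    mat = pd.DataFrame(
        rng.lognormal(0.0, 0.3, size=(40, 200)),
        index=idx, columns=[f"ep{i}" for i in range(200)],
    )
    ann = pd.DataFrame({"sample_id": idx, "group": ["A"] * 20 + ["B"] * 20})
    return mat, ann
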