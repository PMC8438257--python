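import numpy as np
import pytest

from gtvseg.cli_config import _prepare_cohort, desk_cohort_spec, desk_config
from gtvseg.crossval_ensemble import run_full_pipeline
from gtvseg.phantom import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def micro_cohort_spec(n_cases: int, seed: int) -> CohortSpec:
    """A very small cohort (16^3 after cropping) for fast training tests."""
    return CohortSpec(
        n_cases=n_cases,
        master_seed=seed,
        grid_shape=(16, 32, 32),
        spacing_mm=(5.0, 1.25, 1.25),
        diameter_range_mm=(8.0, 14.0),
        noise_sigma=20.0,
    )


@pytest.fixture(scope="session")
def desk_pipeline_runs():
    """Three full desk-scale pipeline runs (n=12, 32^3 grid) at master seeds
    0, 1, 2.  Shared by the ensemble-arity, leakage and ensemble-benefit
    checks; this is the expensive fixture of the suite."""
    out = []
    for seed in (0, 1, 2):
        cfg = desk_config(seed)
        cohort = generate_cohort(desk_cohort_spec(12, seed))
        prepared, _ = _prepare_cohort(cohort, cfg)
        results, runs = run_full_pipeline(
            prepared,
            cfg.unet2d,
            cfg.unet3d,
            scheme_seeds=cfg.scheme_seeds,
            augmentation=cfg.augmentation,
            vote_threshold=cfg.vote_threshold,
        )
        out.append((prepared, results, runs))
    return out
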