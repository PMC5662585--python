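"""Shared fixtures: schedules, calibrated cohorts, repeated-measures simulators."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pigheat import phenotypes as ph
from pigheat.cohort import (
    CohortConfig,
    HSResponseParams,
    default_config,
    default_lines,
    generate_cohort,
)
from pigheat.study_design import build_default_schedule


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


def make_noiseless_config(**over) -> CohortConfig:
    """All randomness off: every derived phenotype equals its configured mean."""
    lines = [
        replace(l, start_bw_sd=0.0, bft_sd=0.0, lea_sd=0.0, loind_sd=0.0)
        for l in default_lines()
    ]
    hs = HSResponseParams(
        tradeoff_slope=0.0, robustness_sd=0.0, residual_sd_bwg=0.0, residual_sd_fi=0.0
    )
    base = dict(
        n_per_cell=2,
        lines=lines,
        hs_response=hs,
        litter_sd=0.0,
        animal_sd=0.0,
        rfi_sd=0.0,
        daily_fi_cv=0.0,
        bw_measurement_sd=0.0,
        adapt_bwg_sd=0.0,
        scan_sd=0.0,
        lean_residual_sd=0.0,
        hcw_sd=0.0,
    )
    base.update(over)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def noiseless_tables(schedule):
    return generate_cohort(make_noiseless_config(), schedule)


@pytest.fixture(scope="session")
def noiseless_derived(noiseless_tables, schedule):
    return ph.derive_all(
        noiseless_tables.bw, noiseless_tables.daily_fi, noiseless_tables.scans, schedule
    )


@pytest.fixture(scope="session")
def calibrated_config():
    return default_config(calibrated=True)


@pytest.fixture(scope="session")
def seeded_cohorts(schedule):
    """20 calibrated study-sized cohorts (~96 pigs) with derived tables."""
    out = []
    for seed in range(20):
        cfg = default_config(calibrated=True, seed=seed, n_per_cell=16)
        tables = generate_cohort(cfg, schedule)
        derived = ph.derive_all(tables.bw, tables.daily_fi, tables.scans, schedule)
        out.append((tables, derived))
    return out


@pytest.fixture(scope="session")
def big_cohort(schedule):
    """~10k-pig cohort for law-of-large-numbers checks and the MC oracle."""
    from pigheat.cohort import calibrate_tradeoff

    cfg = calibrate_tradeoff(-0.5, 0.2, CohortConfig(n_per_cell=1667, seed=11))
    tables = generate_cohort(cfg, schedule)
    derived = ph.derive_all(tables.bw, tables.daily_fi, tables.scans, schedule)
    return cfg, tables, derived


def simulate_repeated(
    n_subj: int,
    T: int,
    cov: np.ndarray,
    seed: int = 0,
    beta_grp: float = 0.8,
) -> pd.DataFrame:
    """Balanced repeated-measures data with one binary factor and given
    within-subject residual covariance."""
    rng = np.random.default_rng(seed)
    grp = rng.choice(["a", "b"], n_subj)
    L = np.linalg.cholesky(cov)
    e = rng.standard_normal((n_subj, T)) @ L.T
    y = 1.0 + beta_grp * (grp == "b")[:, None] + e
    return pd.DataFrame(
        {
            "y": y.ravel(),
            "subject": np.repeat([f"s{i:04d}" for i in range(n_subj)], T),
            "time": np.tile(np.arange(T, dtype=float), n_subj),
            "grp": np.repeat(grp, T),
        }
    )


def ar1_cov(T: int, var: float, rho: float) -> np.ndarray:
    lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    return var * rho**lag


def cs_cov(T: int, var: float, rho: float) -> np.ndarray:
    return var * ((1 - rho) * np.eye(T) + rho * np.ones((T, T)))
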