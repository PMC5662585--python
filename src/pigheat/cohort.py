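"""Synthetic pig cohorts with the study's design and statistical structure.

The generator emulates a 3-line x 2-diet x 2-room grow-finish experiment
under the episodic TN/HS schedule.  Each pig carries persistent latents: a
thermoneutral growth deviation ``u`` (litter + animal), a feed-intake
deviation (its true residual feed intake), and a persistent heat-stress
robustness deviation ``r``.  Per-period true gain is

* TN period:  ``line mean + u``
* HS cycle c: ``line mean + u + loss_bwg_mean[c] + slope * u + r + eps_c``

so a negative ``tradeoff_slope`` makes pigs that grow faster in TN lose more
in HS (the production/robustness trade-off), while ``robustness_sd``
controls how repeatable a pig's HS response is across cycles.  Period feed
intake follows the thermoneutral feed-requirement regression
``b0 + b1*MBW + b2*gain + b3*BFT`` plus a line-level offset, the pig's RFI
deviation, and, in HS, the cycle's total intake drop.  Measured body weights
add weighing noise; daily intake multiplies mean-one lognormal day noise.

Because every observed body-weight-gain statistic is a *linear* function of
the latents and measurement noises, the model-implied correlations between
TN growth and the heat-stress drops have an exact closed form, computed here
by pushing basis unit vectors through the very same boundary-fill code the
analysis uses (:func:`loss_correlation_closed_form`).
:func:`calibrate_tradeoff` inverts that closed form to hit target
correlations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from . import phenotypes as ph
from .study_design import HS, TN, ExperimentSchedule, build_default_schedule

__all__ = [
    "LineParams",
    "HSResponseParams",
    "CohortConfig",
    "CohortTables",
    "GeneratorError",
    "CalibrationError",
    "default_lines",
    "default_config",
    "generate_cohort",
    "loss_correlation_closed_form",
    "calibrate_tradeoff",
]


class GeneratorError(RuntimeError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass
class LineParams:
    """Thermoneutral means and design constants for one genetic line.

    ``n_litters = 0`` means singleton litters (each pig its own litter, used
    for the commercial line whose pedigree is unknown).
    """

    label: str
    bwg_tn_mean: float  # kg/d
    fi_tn_mean: float  # kg/d
    start_bw_mean: float  # kg
    start_bw_sd: float  # kg
    bft_mean: float  # mm, first scan
    lea_mean: float  # cm^2, first scan
    n_litters: int
    loind_mean: float = 56.0  # mm at slaughter
    bft_gain: float = 1.5  # mm between scans
    lea_gain: float = 2.7  # cm^2 between scans
    bft_sd: float = 2.0
    lea_sd: float = 2.5
    loind_sd: float = 3.0

    def __post_init__(self):
        for name in ("bwg_tn_mean", "fi_tn_mean", "start_bw_mean", "bft_mean", "lea_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.label}: {name} must be positive")


@dataclass
class HSResponseParams:
    """Cycle-level HS drops and the latent structure of the HS response."""

    loss_bwg_mean: tuple = (-0.529, -0.294, -0.245)  # kg/d per cycle
    loss_fi_mean: tuple = (-0.662, -0.506, -0.439)  # kg/d per cycle
    tradeoff_slope: float = 0.0  # (kg/d extra drop) per (kg/d TN BWG above line mean)
    robustness_sd: float = 0.0  # kg/d, persistent animal-level HS effect
    residual_sd_bwg: float = 0.12  # kg/d, transient per-cycle gain noise
    residual_sd_fi: float = 0.15  # kg/d, transient per-cycle intake noise

    def __post_init__(self):
        if any(m > 0 for m in self.loss_bwg_mean) or any(m > 0 for m in self.loss_fi_mean):
            raise ValueError("HS loss means must be <= 0 (negative = drop)")
        if self.robustness_sd < 0:
            raise ValueError("robustness_sd must be >= 0")


def default_lines() -> list[LineParams]:
    """Line defaults from the study's least-squares means."""
    return [
        LineParams(
            "commercial", 1.22, 3.22, 59.0, 5.9, 13.5, 33.3, n_litters=0,
            loind_mean=55.6, bft_gain=0.5, lea_gain=4.9,
        ),
        LineParams(
            "lowRFI", 0.720, 2.63, 81.0, 11.0, 17.6, 36.6, n_litters=13,
            loind_mean=59.0, bft_gain=2.4, lea_gain=2.4,
        ),
        LineParams(
            "highRFI", 0.657, 2.77, 81.0, 8.7, 19.3, 37.3, n_litters=10,
            loind_mean=54.8, bft_gain=0.6, lea_gain=0.8,
        ),
    ]


@dataclass
class CohortConfig:
    """Full generator calibration.

    Identical configs (including ``seed``) produce byte-identical tables.
    """

    n_per_cell: int = 16  # pigs per line x diet cell (3x2 cells)
    lines: list = field(default_factory=default_lines)
    hs_response: HSResponseParams = field(default_factory=HSResponseParams)
    diet_fi_effect: float = -0.26  # kg/d FI shift, commercial high-fiber pigs
    litter_sd: float = 0.05  # kg/d, litter effect on BWG and on FI
    animal_sd: float = 0.15  # kg/d, animal TN-gain deviation
    rfi_sd: float = 0.25  # kg/d, animal feed-intake (true RFI) deviation
    daily_fi_cv: float = 0.20  # CV of day-to-day intake noise
    bw_measurement_sd: float = 0.5  # kg, weighing error
    adapt_bwg_sd: float = 0.25  # kg/d, adaptation-period gain noise
    scan_sd: float = 0.5  # mm / cm^2, second-scan increment noise
    lean_residual_sd: float = 1.0  # %, noise around the lean equation
    dressing: float = 0.75  # hot carcass weight / live weight
    hcw_sd: float = 1.5  # kg
    rfi_truth: dict = field(
        default_factory=lambda: {"b0": 2.42, "b1": -0.01, "b2": 0.480, "b3": 0.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for name in (
            "litter_sd", "animal_sd", "rfi_sd", "daily_fi_cv",
            "bw_measurement_sd", "adapt_bwg_sd", "lean_residual_sd", "hcw_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hs_response"]["loss_bwg_mean"] = list(self.hs_response.loss_bwg_mean)
        d["hs_response"]["loss_fi_mean"] = list(self.hs_response.loss_fi_mean)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["lines"] = [LineParams(**l) for l in d.get("lines", [])] or default_lines()
        hs = dict(d.get("hs_response", {}))
        for k in ("loss_bwg_mean", "loss_fi_mean"):
            if k in hs:
                hs[k] = tuple(hs[k])
        d["hs_response"] = HSResponseParams(**hs)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(text))


def default_config(calibrated: bool = True, seed: int = 0, **overrides) -> CohortConfig:
    """Study-calibrated default configuration.

    With ``calibrated=True`` the trade-off slope and robustness SD are solved
    from the closed form so the cohort reproduces the study's pooled
    TN-BWG vs LossBWG correlation (-0.70) and the HS1-HS2 LossBWG
    repeatability (0.36).
    """
    cfg = CohortConfig(seed=seed, **overrides)
    if calibrated:
        cfg = calibrate_tradeoff(-0.70, 0.36, cfg)
    return cfg


# ---------------------------------------------------------------------------
# deterministic substreams
# ---------------------------------------------------------------------------


def _rng_for(seed: int, *tags: str) -> np.random.Generator:
    """Stable named substream: adding pigs never perturbs existing ones."""
    key = tuple(zlib.crc32(t.encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


@dataclass
class CohortTables:
    """Generated raw tables (plus the latent truth, for validation)."""

    pigs: pd.DataFrame
    bw: pd.DataFrame
    daily_fi: pd.DataFrame
    scans: pd.DataFrame
    slaughter: pd.DataFrame
    latents: pd.DataFrame

    _FILES = {
        "pigs": "pigs.csv",
        "bw": "bw.csv",
        "daily_fi": "daily_fi.csv",
        "scans": "scans.csv",
        "slaughter": "slaughter.csv",
        "latents": "latents.csv",
    }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_csv(outdir / fname, index=False)

    @classmethod
    def read(cls, indir) -> "CohortTables":
        indir = Path(indir)
        kw = {}
        for attr, fname in cls._FILES.items():
            p = indir / fname
            kw[attr] = pd.read_csv(p) if p.exists() else pd.DataFrame()
        return cls(**kw)


def _true_bw_at(day, start_bw, adapt_gain, gains, schedule):
    """True BW on an experiment day from piecewise-linear daily gains."""
    a0, a1 = schedule.adaptation_span
    bw = start_bw + adapt_gain * (min(day, a1) - a0)
    for p in schedule.periods:
        lo, hi = p.start_day, p.end_day
        overlap = max(0, min(day, hi) - lo)
        bw += gains[p.label] * overlap
    last_end = schedule.periods[-1].end_day
    if day > last_end:
        bw += gains[schedule.periods[-1].label] * (day - last_end)
    return bw


def _expected_tn_fi_base(line: LineParams, hs: HSResponseParams,
                         truth: dict, schedule: ExperimentSchedule) -> float:
    """Expected TN feed-requirement prediction for a line (no latents)."""
    gains = {}
    cyc = 0
    for p in schedule.periods:
        if p.climate == TN:
            gains[p.label] = line.bwg_tn_mean
        else:
            gains[p.label] = line.bwg_tn_mean + hs.loss_bwg_mean[cyc]
            cyc += 1
    preds = []
    for p in schedule.periods:
        if p.climate != TN:
            continue
        bw_s = _true_bw_at(p.start_day, line.start_bw_mean, line.bwg_tn_mean, gains, schedule)
        bw_e = _true_bw_at(p.end_day, line.start_bw_mean, line.bwg_tn_mean, gains, schedule)
        mbw = ((bw_s + bw_e) / 2.0) ** 0.75
        preds.append(
            truth["b0"] + truth["b1"] * mbw + truth["b2"] * line.bwg_tn_mean
            + truth["b3"] * line.bft_mean
        )
    return float(np.mean(preds))


def _assigned_true_bft(bft1, bft2, schedule):
    """Period -> true backfat, following the scan-assignment rule."""
    labels = [p.label for p in schedule.periods]
    out = {}
    for i, lab in enumerate(labels):
        if i <= 1:
            out[lab] = bft1
        elif i >= len(labels) - 2:
            out[lab] = bft2
        else:
            out[lab] = 0.5 * (bft1 + bft2)
    return out


def generate_cohort(
    config: CohortConfig, schedule: ExperimentSchedule | None = None
) -> CohortTables:
    """Generate one cohort; see the module docstring for the model."""
    schedule = schedule or build_default_schedule()
    hs = config.hs_response
    truth = config.rfi_truth
    n_cycles = len(schedule.hs_cycles)
    if n_cycles > len(hs.loss_bwg_mean):
        raise GeneratorError(
            f"schedule has {n_cycles} HS cycles but only "
            f"{len(hs.loss_bwg_mean)} loss means configured"
        )
    tn_of_cycle = {hs_lab: tn_lab for tn_lab, hs_lab in schedule.tn_hs_pairs()}

    pig_rows, bw_rows, fi_rows, scan_rows, sl_rows, lat_rows = [], [], [], [], [], []
    for line in config.lines:
        # litter effects (stable per litter id)
        if line.n_litters > 0:
            litter_ids = [f"{line.label}-lit{j:02d}" for j in range(1, line.n_litters + 1)]
        else:
            litter_ids = None
        for d_i, diet in enumerate(("low_fiber", "high_fiber")):
            for k in range(config.n_per_cell):
                pig_id = f"{line.label}-{diet}-{k:03d}"
                rng = _rng_for(config.seed, "pig", pig_id)
                if litter_ids is None:
                    litter_id = f"{line.label}-solo-{diet}-{k:03d}"
                else:
                    # deterministic per pig (independent of cohort size)
                    litter_id = litter_ids[(2 * k + d_i) % len(litter_ids)]
                lrng = _rng_for(config.seed, "litter", litter_id)
                lit_bwg = lrng.normal(0.0, config.litter_sd)
                lit_fi = lrng.normal(0.0, config.litter_sd)
                room = 1 + (k % 2)
                if line.label == "commercial":
                    age = 147
                else:
                    age = int(round(rng.normal(147.0, 7.0)))

                # persistent latents
                u = lit_bwg + rng.normal(0.0, config.animal_sd)
                robustness = rng.normal(0.0, hs.robustness_sd) if hs.robustness_sd > 0 else 0.0
                start_bw = line.start_bw_mean + (
                    rng.normal(0.0, line.start_bw_sd) if line.start_bw_sd > 0 else 0.0
                )
                adapt_gain = line.bwg_tn_mean + (
                    rng.normal(0.0, config.adapt_bwg_sd) if config.adapt_bwg_sd > 0 else 0.0
                )
                g_tn = line.bwg_tn_mean + u

                gains, cyc = {}, 0
                for p in schedule.periods:
                    if p.climate == TN:
                        gains[p.label] = g_tn
                    else:
                        eps = rng.normal(0.0, hs.residual_sd_bwg) if hs.residual_sd_bwg > 0 else 0.0
                        gains[p.label] = (
                            g_tn + hs.loss_bwg_mean[cyc]
                            + hs.tradeoff_slope * u + robustness + eps
                        )
                        cyc += 1

                # body-composition truth
                bft1 = line.bft_mean + (rng.normal(0.0, line.bft_sd) if line.bft_sd > 0 else 0.0)
                bft2 = bft1 + line.bft_gain + (
                    rng.normal(0.0, config.scan_sd) if config.scan_sd > 0 else 0.0
                )
                lea1 = line.lea_mean + (rng.normal(0.0, line.lea_sd) if line.lea_sd > 0 else 0.0)
                lea2 = lea1 + line.lea_gain + (
                    rng.normal(0.0, config.scan_sd) if config.scan_sd > 0 else 0.0
                )
                bft_of = _assigned_true_bft(bft1, bft2, schedule)

                # feed-intake level: TN feed-requirement prediction + offsets
                fi_offset = line.fi_tn_mean - _expected_tn_fi_base(line, hs, truth, schedule)
                diet_shift = (
                    config.diet_fi_effect
                    if (line.label == "commercial" and diet == "high_fiber")
                    else 0.0
                )
                hs_eps_fi = {
                    lab: (rng.normal(0.0, hs.residual_sd_fi) if hs.residual_sd_fi > 0 else 0.0)
                    for lab in schedule.hs_cycles
                }
                for attempt in range(101):
                    fi_dev = lit_fi + rng.normal(0.0, config.rfi_sd)
                    period_fi = {}
                    cyc = 0
                    for p in schedule.periods:
                        if p.climate == TN:
                            bw_s = _true_bw_at(p.start_day, start_bw, adapt_gain, gains, schedule)
                            bw_e = _true_bw_at(p.end_day, start_bw, adapt_gain, gains, schedule)
                            mbw = ((bw_s + bw_e) / 2.0) ** 0.75
                            period_fi[p.label] = (
                                truth["b0"] + truth["b1"] * mbw + truth["b2"] * g_tn
                                + truth["b3"] * bft_of[p.label]
                                + fi_offset + diet_shift + fi_dev
                            )
                    for p in schedule.periods:
                        if p.climate == HS:
                            base = period_fi[tn_of_cycle[p.label]]
                            period_fi[p.label] = (
                                base + hs.loss_fi_mean[cyc] + hs_eps_fi[p.label]
                            )
                            cyc += 1
                    adapt_fi = period_fi[schedule.periods[0].label]
                    if all(v > 0 for v in period_fi.values()) and adapt_fi > 0:
                        break
                else:
                    raise GeneratorError(
                        f"pig {pig_id}: could not draw positive feed intake "
                        "after 100 attempts"
                    )

                # tables
                pig_rows.append(
                    {
                        "pig_id": pig_id, "line": line.label, "litter_id": litter_id,
                        "diet": diet, "room": room, "age_at_start": age,
                    }
                )
                for d in schedule.bw_days:
                    true_bw = _true_bw_at(d, start_bw, adapt_gain, gains, schedule)
                    noise = (
                        rng.normal(0.0, config.bw_measurement_sd)
                        if config.bw_measurement_sd > 0 else 0.0
                    )
                    bw_rows.append({"pig_id": pig_id, "day": d, "bw_kg": true_bw + noise})
                sigma = float(np.sqrt(np.log1p(config.daily_fi_cv**2)))
                a0, a1 = schedule.adaptation_span
                last_day = schedule.periods[-1].end_day - 1
                for d in range(a0, last_day + 1):
                    lab = None
                    for p in schedule.periods:
                        if p.start_day <= d < p.end_day:
                            lab = p.label
                            break
                    mean_fi = period_fi[lab] if lab else adapt_fi
                    mult = (
                        float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                        if sigma > 0 else 1.0
                    )
                    fi_rows.append({"pig_id": pig_id, "day": d, "fi_kg": mean_fi * mult})
                scan_rows.append(
                    {"pig_id": pig_id, "day": schedule.scan_days[0],
                     "bft_mm": bft1, "lea_cm2": lea1}
                )
                scan_rows.append(
                    {"pig_id": pig_id, "day": schedule.scan_days[1],
                     "bft_mm": bft2, "lea_cm2": lea2}
                )
                bw_sl = _true_bw_at(schedule.slaughter_day, start_bw, adapt_gain, gains, schedule)
                loind = line.loind_mean + (
                    rng.normal(0.0, line.loind_sd) if line.loind_sd > 0 else 0.0
                )
                lean = ph.pct_lean(max(bft2, 0.0), max(loind, 0.0)) + (
                    rng.normal(0.0, config.lean_residual_sd)
                    if config.lean_residual_sd > 0 else 0.0
                )
                hcw = config.dressing * bw_sl + (
                    rng.normal(0.0, config.hcw_sd) if config.hcw_sd > 0 else 0.0
                )
                sl_rows.append(
                    {"pig_id": pig_id, "hcw_kg": hcw, "loind_mm": loind, "lean_pct": lean}
                )
                lat_rows.append(
                    {
                        "pig_id": pig_id, "tn_bwg": g_tn, "tn_fi_dev": fi_dev,
                        "robustness": robustness, "u": u, "start_bw": start_bw,
                        **{f"gain_{lab}": gains[lab] for lab in gains},
                    }
                )

    return CohortTables(
        pigs=pd.DataFrame(pig_rows),
        bw=pd.DataFrame(bw_rows),
        daily_fi=pd.DataFrame(fi_rows),
        scans=pd.DataFrame(scan_rows),
        slaughter=pd.DataFrame(sl_rows),
        latents=pd.DataFrame(lat_rows),
    )


# ---------------------------------------------------------------------------
# closed-form trade-off correlations and calibration
# ---------------------------------------------------------------------------


def _observed_bwg_vector(schedule, gains, eta):
    """Observed per-period BWG for one pseudo-pig (linear map evaluation)."""
    rows = []
    for d in schedule.bw_days:
        if d < schedule.periods[0].start_day:
            continue  # pre-anchor weighings never enter the boundary fill
        true_bw = 0.0
        for p in schedule.periods:
            true_bw += gains[p.label] * max(0, min(d, p.end_day) - p.start_day)
        rows.append({"pig_id": "x", "day": d, "bw_kg": true_bw + eta.get(d, 0.0)})
    completed = ph.estimate_boundary_bw(pd.DataFrame(rows), schedule)
    bw = dict(zip(completed["day"], completed["bw_kg"]))
    return np.array(
        [(bw[p.end_day] - bw[p.start_day]) / p.span for p in schedule.periods]
    )


_BASIS_CACHE: dict = {}


def _schedule_key(schedule: ExperimentSchedule) -> tuple:
    return (
        tuple((p.label, p.climate, p.start_day, p.end_day) for p in schedule.periods),
        tuple(schedule.bw_days),
    )


def _bwg_coefficient_matrix(schedule: ExperimentSchedule, slope: float) -> tuple:
    """Coefficients of observed period BWG on the latent/noise basis.

    Basis order: u, r, eps_1..eps_C, eta_d for each post-anchor weighing day.
    Exact because the whole observation map is linear in the basis; only the
    ``u`` column depends (affinely) on the trade-off slope, so the matrix is
    cached at two slope values and interpolated.
    """
    key = _schedule_key(schedule)
    if key in _BASIS_CACHE:
        m0, dm, names = _BASIS_CACHE[key]
        return m0 + slope * dm, names
    m0, names = _bwg_coefficient_matrix_direct(schedule, 0.0)
    m1, _ = _bwg_coefficient_matrix_direct(schedule, 1.0)
    _BASIS_CACHE[key] = (m0, m1 - m0, names)
    return m0 + slope * (m1 - m0), names


def _bwg_coefficient_matrix_direct(schedule: ExperimentSchedule, slope: float) -> tuple:
    hs_labels = schedule.hs_cycles
    eta_days = [d for d in schedule.bw_days if d >= schedule.periods[0].start_day]
    names = ["u", "r"] + [f"eps_{l}" for l in hs_labels] + [f"eta_{d}" for d in eta_days]
    cols = []
    zero_g = {p.label: 0.0 for p in schedule.periods}

    def gains_for(u=0.0, r=0.0, eps=None):
        g = dict(zero_g)
        cyc = 0
        for p in schedule.periods:
            if p.climate == TN:
                g[p.label] = u
            else:
                e = eps.get(p.label, 0.0) if eps else 0.0
                g[p.label] = u + slope * u + r + e
                cyc += 1
        return g

    cols.append(_observed_bwg_vector(schedule, gains_for(u=1.0), {}))
    cols.append(_observed_bwg_vector(schedule, gains_for(r=1.0), {}))
    for lab in hs_labels:
        cols.append(_observed_bwg_vector(schedule, gains_for(eps={lab: 1.0}), {}))
    for d in eta_days:
        cols.append(_observed_bwg_vector(schedule, zero_g, {d: 1.0}))
    return np.column_stack(cols), names  # (n_periods, n_basis)


@dataclass
class TradeoffCorrelations:
    """Model-implied correlations between TN growth and HS drops."""

    per_cycle_r: list  # corr(BWG TN_c, Loss_c), one per cycle
    pooled_r: float  # period-adjusted pooled correlation
    cycle_repeatability_r: float  # corr(Loss_1, Loss_2)


def loss_correlation_closed_form(
    config: CohortConfig, schedule: ExperimentSchedule | None = None
) -> TradeoffCorrelations:
    """Exact correlations implied by the linear generative model.

    Includes the propagation of BW weighing error through the boundary fill;
    that propagation is what lets a strong pooled trade-off coexist with
    moderate cycle-to-cycle repeatability of the drop.
    """
    schedule = schedule or build_default_schedule()
    hs = config.hs_response
    M, names = _bwg_coefficient_matrix(schedule, hs.tradeoff_slope)
    var = np.zeros(len(names))
    tau2 = config.litter_sd**2 + config.animal_sd**2
    for i, nm in enumerate(names):
        if nm == "u":
            var[i] = tau2
        elif nm == "r":
            var[i] = hs.robustness_sd**2
        elif nm.startswith("eps_"):
            var[i] = hs.residual_sd_bwg**2
        else:
            var[i] = config.bw_measurement_sd**2

    labels = [p.label for p in schedule.periods]
    row = {lab: M[i] for i, lab in enumerate(labels)}
    pairs = schedule.tn_hs_pairs()
    xs = [row[tn] for tn, _ in pairs]
    ys = [row[h] - row[tn] for tn, h in pairs]

    def cov(a, b):
        return float(np.sum(a * b * var))

    per_cycle = [cov(x, y) / np.sqrt(cov(x, x) * cov(y, y)) for x, y in zip(xs, ys)]
    pooled = sum(cov(x, y) for x, y in zip(xs, ys)) / np.sqrt(
        sum(cov(x, x) for x in xs) * sum(cov(y, y) for y in ys)
    )
    if len(ys) >= 2:
        rep = cov(ys[0], ys[1]) / np.sqrt(cov(ys[0], ys[0]) * cov(ys[1], ys[1]))
    else:
        rep = np.nan
    return TradeoffCorrelations(per_cycle, float(pooled), float(rep))


def calibrate_tradeoff(
    target_pooled_r: float,
    target_cycle_r: float,
    config: CohortConfig,
    schedule: ExperimentSchedule | None = None,
    tol: float = 0.05,
) -> CohortConfig:
    """Choose (tradeoff_slope, robustness_sd, residual_sd_bwg) for two targets.

    Targets: the pooled, period-adjusted correlation between TN BWG and the
    next cycle's LossBWG, and the Loss_1/Loss_2 repeatability.  First the
    slope and the persistent robustness SD are solved with the transient
    noise held fixed; if the repeatability target lies below the
    shared-mechanism floor, robustness is pinned at zero and the transient
    per-cycle noise SD absorbs the difference.  The closest solution is
    accepted when both implied correlations are within ``tol`` of target;
    otherwise :class:`CalibrationError` is raised (e.g. no
    non-negative-variance solution exists for the pair).  Zero targets
    request the independence configuration (slope 0, robustness 0) of the
    mechanism itself.
    """
    for t in (target_pooled_r, target_cycle_r):
        if not -1.0 < t < 1.0:
            raise CalibrationError("targets must lie in (-1, 1)")
    schedule = schedule or build_default_schedule()
    if target_pooled_r == 0.0 and target_cycle_r == 0.0:
        hs = replace(config.hs_response, tradeoff_slope=0.0, robustness_sd=0.0)
        return replace(config, hs_response=hs)

    def residuals_for(make_hs):
        def residuals(x):
            cc = loss_correlation_closed_form(
                replace(config, hs_response=make_hs(x)), schedule
            )
            return [
                cc.pooled_r - target_pooled_r,
                cc.cycle_repeatability_r - target_cycle_r,
            ]
        return residuals

    def solve(make_hs, x0s, lo, hi):
        best = None
        for x0 in x0s:
            sol = least_squares(
                residuals_for(make_hs), x0=x0, bounds=(lo, hi),
                xtol=1e-12, ftol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.cost < 1e-14:
                break
        return best

    # stage 1: adjust (slope, robustness_sd), transient noise held fixed
    def hs_slope_rho(x):
        return replace(
            config.hs_response, tradeoff_slope=float(x[0]), robustness_sd=float(x[1])
        )

    rho0 = max(config.hs_response.robustness_sd, 0.05)
    best = solve(
        hs_slope_rho, [[-1.0, rho0], [0.5, rho0], [-3.0, rho0]],
        [-20.0, 0.0], [20.0, 5.0],
    )
    if np.sqrt(2 * best.cost) <= 1e-6:
        return replace(config, hs_response=hs_slope_rho(best.x))

    # stage 2: repeatability below the shared-mechanism floor -- set the
    # persistent robustness effect to zero and let the transient per-cycle
    # noise SD absorb the difference instead
    def hs_slope_eps(x):
        return replace(
            config.hs_response, tradeoff_slope=float(x[0]), robustness_sd=0.0,
            residual_sd_bwg=float(x[1]),
        )

    eps0 = max(config.hs_response.residual_sd_bwg, 0.05)
    best2 = solve(
        hs_slope_eps, [[-1.0, eps0], [-3.0, 2 * eps0], [0.5, eps0]],
        [-20.0, 1e-6], [20.0, 5.0],
    )
    cand = [(best, hs_slope_rho), (best2, hs_slope_eps)]
    cand.sort(key=lambda t: t[0].cost)
    winner, make_hs = cand[0]
    if np.max(np.abs(winner.fun)) <= tol:
        return replace(config, hs_response=make_hs(winner.x))
    raise CalibrationError(
        f"no feasible (tradeoff_slope, robustness_sd, residual_sd_bwg) for "
        f"targets ({target_pooled_r}, {target_cycle_r}); best residuals "
        f"{best.fun} / {best2.fun}"
    )
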