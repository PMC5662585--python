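"""Thermoneutral-anchored residual feed intake and feed-requirement models.

Residual feed intake (RFI) is the difference between a pig's feed intake
and the intake predicted from its maintenance (metabolic body weight),
growth, and backfat.  Here the prediction equation is fitted by ordinary
least squares on the thermoneutral (TN) pig-period observations only,

    FI = b0 + b1 * MBW + b2 * BWG + b3 * BFT + e,

and then applied to *all* periods, TN and HS alike, so the HS residual
measures how much a pig ate below or above what it would have eaten in TN
given its (heat-depressed) growth, weight, and fatness.  On the TN rows the
applied residual reproduces the fitting residuals identically, so TN RFI
averages exactly zero over the fitted cohort while HS RFI is free.

The companion feed-requirement model replaces the single BWG slope by a
line-by-climate-specific slope and adds design effects plus a random litter
intercept, estimated by REML through the mixed-model engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lmm import LmmFit, ModelSpec, SingularFitError, fit_lmm

__all__ = [
    "RFICoefficients",
    "fit_rfi_tn",
    "apply_rfi",
    "residual_growth",
    "fit_feed_requirements",
]

_PREDICTORS = ["mbw_kg075", "bwg_kgd", "bft_mm"]
_COEF_NAMES = ["b0", "b1", "b2", "b3"]


@dataclass
class RFICoefficients:
    """OLS fit of the TN feed-intake prediction equation."""

    b: dict  # b0 (kg/d), b1 (kg/d per kg^0.75), b2 (kg feed / kg gain), b3 (kg/d per mm)
    se: dict
    vcov: np.ndarray
    r_squared: float
    r_squared_adj: float
    n_obs: int
    response: str = "fi_kgd"

    def predict(self, phenotypes: pd.DataFrame) -> np.ndarray:
        X = phenotypes[_PREDICTORS].to_numpy(dtype=float)
        b = np.array([self.b[k] for k in _COEF_NAMES])
        return b[0] + X @ b[1:]

    def to_dict(self) -> dict:
        return {
            "coefficients": self.b,
            "se": self.se,
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "n_obs": self.n_obs,
            "response": self.response,
        }


def _ols_fit(data: pd.DataFrame, response: str, predictors: list) -> RFICoefficients:
    cols = [response] + predictors
    d = data.dropna(subset=cols)
    n = len(d)
    if n < 5:
        raise ValueError(f"need at least 5 complete observations, got {n}")
    X = sm.add_constant(d[predictors].to_numpy(dtype=float), has_constant="add")
    for j, name in enumerate(predictors):
        if np.unique(X[:, j + 1]).size < 2:
            raise SingularFitError(f"regressor {name!r} has fewer than 2 distinct values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        bad = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 0.999
        ]
        raise SingularFitError(f"singular design; collinear columns: {bad or predictors}")
    res = sm.OLS(d[response].to_numpy(dtype=float), X).fit()
    b = dict(zip(_COEF_NAMES, map(float, res.params)))
    se = dict(zip(_COEF_NAMES, map(float, res.bse)))
    return RFICoefficients(
        b=b,
        se=se,
        vcov=np.asarray(res.cov_params()),
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        n_obs=n,
        response=response,
    )


def fit_rfi_tn(phenotypes: pd.DataFrame, climate: str = "TN") -> RFICoefficients:
    """Fit the feed-intake prediction equation on one climate's pig-periods.

    Pools all pig-period rows of the given climate with equal weight (a 4-day
    HS period counts the same as a 7-day TN period).  The residuals are the
    TN-anchored RFI values for those rows.
    """
    rows = phenotypes[phenotypes["climate"] == climate]
    if rows.empty:
        raise ValueError(f"no rows with climate {climate!r}")
    return _ols_fit(rows, "fi_kgd", _PREDICTORS)


def apply_rfi(coef: RFICoefficients, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Fill ``rfi_kgd = FI - predicted FI`` for every TN and HS row.

    Rows missing the assigned backfat (or any predictor) are left NaN.  On
    the rows the coefficients were fitted to, the result equals the OLS
    residuals elementwise.
    """
    out = phenotypes.copy()
    ok = out[_PREDICTORS + ["fi_kgd"]].notna().all(axis=1)
    pred = coef.predict(out[ok])
    out.loc[ok, "rfi_kgd"] = out.loc[ok, "fi_kgd"].to_numpy(dtype=float) - pred
    return out


def residual_growth(
    phenotypes: pd.DataFrame, climate: str = "TN"
) -> tuple[RFICoefficients, pd.DataFrame]:
    """Residual growth: swap FI and BWG in the prediction equation.

    OLS of BWG on {1, MBW, FI, BFT} over the given climate's rows; the TN
    coefficients are then applied to all rows, so the HS residual measures
    growth above/below the TN expectation at the pig's (reduced) intake.
    Returns the coefficients and the phenotype frame with a
    ``resid_growth_kgd`` column.
    """
    rows = phenotypes[phenotypes["climate"] == climate]
    coef = _ols_fit(rows, "bwg_kgd", ["mbw_kg075", "fi_kgd", "bft_mm"])
    out = phenotypes.copy()
    ok = out[["mbw_kg075", "fi_kgd", "bft_mm", "bwg_kgd"]].notna().all(axis=1)
    X = out.loc[ok, ["mbw_kg075", "fi_kgd", "bft_mm"]].to_numpy(dtype=float)
    b = np.array([coef.b[k] for k in _COEF_NAMES])
    pred = b[0] + X @ b[1:]
    out.loc[ok, "resid_growth_kgd"] = out.loc[ok, "bwg_kgd"].to_numpy(dtype=float) - pred
    return coef, out


_FEEDREQ_REFS = {"climate": "HS", "diet": "low_fiber", "line": "highRFI", "room": "2"}


def fit_feed_requirements(
    phenotypes: pd.DataFrame, pigs: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, LmmFit]:
    """Line- and climate-specific feed requirements for growth.

    REML mixed model of period FI on line, climate, diet, room, age, MBW and
    BFT with a separate BWG slope per line-climate cell and a random litter
    intercept nested in line; residuals independent.  Reference levels (HS,
    low fiber, high-RFI line, room 2) are reported as zero rows so the
    estimate table is directly comparable across cohorts.
    """
    meta_cols = ["line", "litter_id", "diet", "room", "age_at_start"]
    data = phenotypes.drop(columns=meta_cols, errors="ignore").merge(
        pigs[["pig_id"] + meta_cols], on="pig_id", how="inner"
    )
    data["room"] = data["room"].astype(str)
    data = data.dropna(subset=["fi_kgd", "bwg_kgd", "mbw_kg075", "bft_mm"])
    spec = ModelSpec(
        response="fi_kgd",
        fixed=[
            "climate", "diet", "line", "room", "age_at_start", "mbw_kg075",
            "bwg_kgd*climate*line", "bft_mm",
        ],
        random=["litter_id(line)"],
        repeated=None,
        ref_levels=_FEEDREQ_REFS,
        categorical=("line", "climate", "diet", "room"),
    )
    fit = fit_lmm(spec, data, seed=seed)
    fe = dict(zip(fit.fe_names, fit.beta))
    fe_se = dict(zip(fit.fe_names, np.sqrt(np.diag(fit.fe_vcov))))

    def row(effect, name, climate="", diet="", line="", room=""):
        return {
            "effect": effect, "climate": climate, "diet": diet, "line": line,
            "room": room,
            "estimate": float(fe.get(name, 0.0)),
            "se": float(fe_se[name]) if name in fe_se else np.nan,
        }

    rows = [row("Intercept", "(Intercept)")]
    rows.append(row("Climate", "climate[TN]", climate="TN"))
    rows.append(row("Climate", "", climate="HS"))
    rows.append(row("Diet", "diet[high_fiber]", diet="high_fiber"))
    rows.append(row("Diet", "", diet="low_fiber"))
    for line in ("commercial", "lowRFI"):
        rows.append(row("Line", f"line[{line}]", line=line))
    rows.append(row("Line", "", line="highRFI"))
    rows.append(row("Room", "room[1]", room="1"))
    rows.append(row("Room", "", room="2"))
    rows.append(row("Age", "age_at_start"))
    rows.append(row("MBW", "mbw_kg075"))
    for climate in ("TN", "HS"):
        for line in ("commercial", "lowRFI", "highRFI"):
            rows.append(
                row(
                    "BWG x C x L",
                    f"bwg_kgd:climate[{climate}]:line[{line}]",
                    climate=climate, line=line,
                )
            )
    rows.append(row("BackFat", "bft_mm"))
    return pd.DataFrame(rows), fit
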