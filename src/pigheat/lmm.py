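"""REML engine for repeated-measures linear mixed models.

Fits ``y = X beta + Z b + e`` where ``b`` holds independent random
intercepts (e.g. litter nested in line, animal) and the residuals of each
subject follow a structured T x T covariance over the repeated levels
(periods):

* ``iid``    sigma^2 I
* ``cs``     compound symmetry (common variance, common correlation)
* ``ar1``    homogeneous first-order autoregressive
* ``arh1``   heterogeneous AR(1) (one variance per level)
* ``toep``   Toeplitz (one correlation per lag)
* ``un``     unstructured
* ``sppow``  spatial power, ``corr = rho^{|t_i - t_j|}`` for unequally
  spaced times

The REML log-likelihood is maximised over an unconstrained parameterisation
(log variances; Fisher-z for AR1/TOEP correlations; a scaled sigmoid keeping
the CS correlation above its -1/(T-1) bound; logit for the spatial-power
rho; log-Cholesky for UN; Toeplitz proposals that are not positive definite
are rejected inside the optimiser).  Fixed effects are profiled out by GLS.
Likelihoods are computed block-wise over independent subject groups (pigs
sharing a random-effect level, e.g. a litter, are merged into one block) and
identical block patterns share one Cholesky factor, so balanced designs cost
O(T^3) per evaluation rather than O(n^3).

Fixed-effect formulas use a small term language:

* ``"line"``              categorical main effect (treatment coding)
* ``"age"``               covariate
* ``"period(climate)"``   period nested in climate (one reference per group)
* ``"line*climate"``      interaction of reduced dummy codings
* ``"bwg*line*climate"``  covariate with a separate slope per factor cell
  (full-cell coding; no bare-covariate main effect should then be listed)

Model selection ranks converged fits by AICc and compares the two best by a
REML likelihood-ratio test when nested; interaction pruning drops the least
significant interaction at a time until all remaining ones beat the
threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ModelSpec",
    "LmmFit",
    "LmmError",
    "SingularFitError",
    "DesignBuilder",
    "build_design",
    "fit_lmm",
    "build_problem",
    "select_structure",
    "prune_interactions",
    "ls_means",
    "fce_bwg_slopes",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-10
_BIG = 1e12


class LmmError(RuntimeError):
    pass


class SingularFitError(LmmError):
    pass


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _as_str(s: pd.Series) -> pd.Series:
    return s.astype(str)


class _Component:
    """One token of a term: categorical, nested categorical, or covariate."""

    def __init__(self, token: str, data: pd.DataFrame, categorical: set):
        token = token.strip()
        self.token = token
        if token.endswith(")") and "(" in token:
            inner, outer = token[:-1].split("(")
            self.kind = "nested"
            self.col, self.group_col = inner.strip(), outer.strip()
        else:
            self.col = token
            if token in data.columns and (
                token in categorical
                or data[token].dtype == object
                or isinstance(data[token].dtype, pd.CategoricalDtype)
                or data[token].dtype == bool
            ):
                self.kind = "cat"
            else:
                self.kind = "num"
        if self.col not in data.columns:
            raise LmmError(f"term component {token!r}: column {self.col!r} not in data")
        if self.kind == "cat":
            self.levels = sorted(_as_str(data[self.col]).unique())
        elif self.kind == "nested":
            pairs = (
                pd.DataFrame(
                    {"g": _as_str(data[self.group_col]), "l": _as_str(data[self.col])}
                )
                .drop_duplicates()
                .sort_values(["g", "l"])
            )
            self.groups = {}
            for g, sub in pairs.groupby("g", sort=True):
                self.groups[g] = list(sub["l"])

    def coding(self, df: pd.DataFrame, reduced: bool, ref: str | None = None):
        """(column names, matrix) for this component."""
        n = len(df)
        if self.kind == "num":
            return [self.col], np.asarray(df[self.col], dtype=float)[:, None]
        if self.kind == "cat":
            vals = _as_str(df[self.col]).to_numpy()
            levels = self.levels
            if reduced:
                ref = ref if ref is not None else levels[0]
                levels = [l for l in self.levels if l != ref]
            names = [f"{self.col}[{l}]" for l in levels]
            mat = (
                np.column_stack([(vals == l).astype(float) for l in levels])
                if levels
                else np.empty((n, 0))
            )
            return names, mat
        # nested
        gv = _as_str(df[self.group_col]).to_numpy()
        lv = _as_str(df[self.col]).to_numpy()
        names, cols = [], []
        for g, levels in self.groups.items():
            keep = levels[1:] if reduced else levels
            for l in keep:
                names.append(f"{self.col}[{l}]({self.group_col}={g})")
                cols.append(((gv == g) & (lv == l)).astype(float))
        mat = np.column_stack(cols) if cols else np.empty((n, 0))
        return names, mat


class _Term:
    def __init__(self, term: str, data: pd.DataFrame, categorical: set, ref_levels: dict):
        self.term = term
        self.components = [_Component(tok, data, categorical) for tok in term.split("*")]
        self.ref_levels = ref_levels
        self.has_num = any(c.kind == "num" for c in self.components)
        self.keep: np.ndarray | None = None  # non-degenerate columns, set at fit

    def _raw(self, df: pd.DataFrame):
        # with a covariate present, factors get full-cell coding
        reduced = not self.has_num
        names_parts, mats = [], []
        for c in self.components:
            nm, m = c.coding(df, reduced=reduced, ref=self.ref_levels.get(c.col))
            names_parts.append(nm)
            mats.append(m)
        names, out = names_parts[0], mats[0]
        for nm, m in zip(names_parts[1:], mats[1:]):
            names = [f"{a}:{b}" for a in names for b in nm]
            out = (out[:, :, None] * m[:, None, :]).reshape(len(df), -1)
        return names, out

    def fit_columns(self, df: pd.DataFrame):
        names, mat = self._raw(df)
        self.keep = np.asarray(mat.any(axis=0)) if mat.size else np.zeros(0, bool)
        return [n for n, k in zip(names, self.keep) if k], mat[:, self.keep]

    def build(self, df: pd.DataFrame):
        _, mat = self._raw(df)
        return mat[:, self.keep]


@dataclass
class DesignBuilder:
    """Fitted design encoder; rebuilds X for new rows (LS-mean grids)."""

    terms: list
    colnames: list
    term_index: dict  # term string -> column indices
    categorical_vars: dict  # var -> sorted levels (all factors in the model)
    covariate_means: dict
    observed_combos: pd.DataFrame

    def build(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        cols = [np.ones((n, 1))]
        for t in self.terms:
            cols.append(t.build(df))
        return np.hstack(cols)


def build_design(
    data: pd.DataFrame,
    terms: list,
    ref_levels: dict | None = None,
    categorical: set | None = None,
) -> tuple[np.ndarray, DesignBuilder]:
    """Build the fixed-effect design matrix with an intercept.

    Returns ``(X, builder)``.  Raises :class:`SingularFitError` naming the
    offending columns when the design is rank deficient.
    """
    ref_levels = ref_levels or {}
    categorical = set(categorical or ())
    term_objs, colnames, index = [], ["(Intercept)"], {}
    mats = [np.ones((len(data), 1))]
    cat_vars, cov_means = {}, {}
    for term in terms:
        t = _Term(term, data, categorical, ref_levels)
        names, mat = t.fit_columns(data)
        index[term] = list(range(len(colnames), len(colnames) + len(names)))
        colnames.extend(names)
        mats.append(mat)
        term_objs.append(t)
        for c in t.components:
            if c.kind == "cat":
                cat_vars[c.col] = c.levels
            elif c.kind == "nested":
                cat_vars.setdefault(
                    c.col, sorted({l for ls in c.groups.values() for l in ls})
                )
                cat_vars.setdefault(c.group_col, sorted(c.groups.keys()))
            else:
                cov_means[c.col] = float(np.mean(data[c.col]))
    X = np.hstack(mats)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [colnames[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise SingularFitError(
            f"rank-deficient fixed-effect design (rank {rank} < {X.shape[1]}); "
            f"near-collinear columns: {bad}"
        )
    combos = (
        data[list(cat_vars)].astype(str).drop_duplicates().reset_index(drop=True)
        if cat_vars
        else pd.DataFrame()
    )
    builder = DesignBuilder(
        terms=term_objs,
        colnames=colnames,
        term_index=index,
        categorical_vars=cat_vars,
        covariate_means=cov_means,
        observed_combos=combos,
    )
    return X, builder


# ---------------------------------------------------------------------------
# covariance structures
# ---------------------------------------------------------------------------


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class _Structure:
    kind = ""

    def __init__(self, T: int, times: np.ndarray):
        self.T = T
        self.times = np.asarray(times, dtype=float)
        self.lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        self.dist = np.abs(np.subtract.outer(self.times, self.times))

    @property
    def n_params(self) -> int:
        raise NotImplementedError

    def build(self, theta: np.ndarray):
        raise NotImplementedError

    def init(self, S: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self, theta: np.ndarray) -> dict:
        return {}

    @staticmethod
    def _mean_lag_corr(S, lag_mat, k):
        d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        C = S / np.outer(d, d)
        vals = C[lag_mat == k]
        return float(np.clip(np.mean(vals), -0.95, 0.95)) if vals.size else 0.0


class _IID(_Structure):
    kind = "iid"
    n_params = 1

    def build(self, th):
        return (np.exp(th[0]) + _VAR_FLOOR) * np.eye(self.T)

    def init(self, S):
        return np.array([np.log(max(np.mean(np.diag(S)), 1e-8))])

    def describe(self, th):
        return {"var": float(np.exp(th[0]))}


class _AR1(_Structure):
    kind = "ar1"
    n_params = 2

    def build(self, th):
        v = np.exp(th[0]) + _VAR_FLOOR
        rho = np.tanh(th[1])
        return v * rho ** self.lag

    def init(self, S):
        r = self._mean_lag_corr(S, self.lag, 1)
        return np.array([np.log(max(np.mean(np.diag(S)), 1e-8)), np.arctanh(r)])

    def describe(self, th):
        return {"var": float(np.exp(th[0])), "rho": float(np.tanh(th[1]))}


class _ARH1(_Structure):
    kind = "arh1"

    @property
    def n_params(self):
        return self.T + 1

    def build(self, th):
        sd = np.sqrt(np.exp(th[: self.T]) + _VAR_FLOOR)
        rho = np.tanh(th[self.T])
        return np.outer(sd, sd) * rho ** self.lag

    def init(self, S):
        r = self._mean_lag_corr(S, self.lag, 1)
        return np.append(np.log(np.clip(np.diag(S), 1e-8, None)), np.arctanh(r))

    def describe(self, th):
        return {
            "var": [float(v) for v in np.exp(th[: self.T])],
            "rho": float(np.tanh(th[self.T])),
        }


class _CS(_Structure):
    kind = "cs"
    n_params = 2

    def _rho(self, z):
        lo = -1.0 / (self.T - 1) + 1e-6 if self.T > 1 else -1 + 1e-6
        hi = 1.0 - 1e-6
        return lo + (hi - lo) * _expit(z)

    def build(self, th):
        v = np.exp(th[0]) + _VAR_FLOOR
        rho = self._rho(th[1])
        return v * ((1 - rho) * np.eye(self.T) + rho)

    def init(self, S):
        d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        C = S / np.outer(d, d)
        off = C[~np.eye(self.T, dtype=bool)]
        lo = -1.0 / (self.T - 1) + 1e-6 if self.T > 1 else -1 + 1e-6
        r = float(np.clip(np.mean(off), lo + 1e-3, 0.95)) if off.size else 0.0
        frac = np.clip((r - lo) / (1 - 1e-6 - lo), 1e-4, 1 - 1e-4)
        return np.array(
            [np.log(max(np.mean(np.diag(S)), 1e-8)), np.log(frac / (1 - frac))]
        )

    def describe(self, th):
        return {"var": float(np.exp(th[0])), "rho": float(self._rho(th[1]))}


class _TOEP(_Structure):
    kind = "toep"

    @property
    def n_params(self):
        return self.T

    def build(self, th):
        v = np.exp(th[0]) + _VAR_FLOOR
        corr = np.eye(self.T)
        for k in range(1, self.T):
            corr[self.lag == k] = np.tanh(th[k])
        if np.linalg.eigvalsh(corr)[0] <= 1e-8:
            return None  # rejected: outside the PD region
        return v * corr

    def init(self, S):
        th = [np.log(max(np.mean(np.diag(S)), 1e-8))]
        for k in range(1, self.T):
            th.append(np.arctanh(0.8 * self._mean_lag_corr(S, self.lag, k)))
        return np.array(th)

    def describe(self, th):
        return {
            "var": float(np.exp(th[0])),
            "lag_corr": [float(np.tanh(t)) for t in th[1:]],
        }


class _UN(_Structure):
    kind = "un"

    @property
    def n_params(self):
        return self.T * (self.T + 1) // 2

    def _chol(self, th):
        L = np.zeros((self.T, self.T))
        k = 0
        for i in range(self.T):
            for j in range(i + 1):
                L[i, j] = np.exp(th[k]) if i == j else th[k]
                k += 1
        return L

    def build(self, th):
        L = self._chol(th)
        return L @ L.T + _VAR_FLOOR * np.eye(self.T)

    def init(self, S):
        S = S + 1e-6 * max(np.mean(np.diag(S)), 1e-8) * np.eye(self.T)
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(np.diag(np.clip(np.diag(S), 1e-8, None)))
        th = []
        for i in range(self.T):
            for j in range(i + 1):
                th.append(np.log(max(L[i, j], 1e-6)) if i == j else L[i, j])
        return np.array(th)

    def describe(self, th):
        L = self._chol(th)
        return {"cov": (L @ L.T).tolist()}


class _SPPOW(_Structure):
    kind = "sppow"
    n_params = 2

    def build(self, th):
        v = np.exp(th[0]) + _VAR_FLOOR
        rho = _expit(th[1]) * (1 - 2e-9) + 1e-9
        return v * rho ** self.dist

    def init(self, S):
        r1 = max(self._mean_lag_corr(S, self.lag, 1), 1e-3)
        dt = np.median(self.dist[self.lag == 1]) if self.T > 1 else 1.0
        rho = float(np.clip(r1 ** (1.0 / max(dt, 1e-6)), 1e-3, 1 - 1e-3))
        return np.array(
            [np.log(max(np.mean(np.diag(S)), 1e-8)), np.log(rho / (1 - rho))]
        )

    def describe(self, th):
        return {"var": float(np.exp(th[0])), "rho": float(_expit(th[1]))}


_STRUCTURES = {c.kind: c for c in (_IID, _AR1, _ARH1, _CS, _TOEP, _UN, _SPPOW)}

#: marginal-covariance nesting relation used for likelihood-ratio tests
_NESTED_IN = {
    "iid": {"cs", "ar1", "arh1", "toep", "un", "sppow"},
    "ar1": {"arh1", "toep", "un"},
    "cs": {"toep", "un"},
    "arh1": {"un"},
    "toep": {"un"},
    "sppow": {"un"},
    "un": set(),
}


# ---------------------------------------------------------------------------
# model specification and REML problem
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative mixed-model specification.

    ``repeated`` is ``{"subject": col, "time": numeric col, "structure":
    kind}`` or None for independent residuals.  ``random`` lists random
    intercept groupings, each a column name or ``"a(b)"`` for nesting.
    ``animal_intercept``: "auto" adds a random subject intercept for the
    ar1/arh1 structures (the convention for this study's repeated models),
    "always"/"never" force it.
    """

    response: str
    fixed: list
    random: list = field(default_factory=list)
    repeated: dict | None = None
    ref_levels: dict = field(default_factory=dict)
    categorical: tuple = ()
    animal_intercept: str = "auto"

    def with_structure(self, kind: str) -> "ModelSpec":
        rep = dict(self.repeated or {})
        rep["structure"] = kind
        return replace(self, repeated=rep)


def _random_labels(data: pd.DataFrame, term: str) -> pd.Series:
    if term.endswith(")") and "(" in term:
        inner, outer = term[:-1].split("(")
        return (
            _as_str(data[outer.strip()]) + "/" + _as_str(data[inner.strip()])
        ).rename(term)
    return _as_str(data[term]).rename(term)


class _Problem:
    """Prepared REML optimisation problem (data, design, blocks, structure)."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        rep = spec.repeated
        data = data.reset_index(drop=True)
        y_raw = np.asarray(data[spec.response], dtype=float)
        data = data[np.isfinite(y_raw)].reset_index(drop=True)
        if rep is not None:
            subject, timecol = rep["subject"], rep["time"]
            data = data.sort_values([subject, timecol]).reset_index(drop=True)
            times = np.sort(data[timecol].unique())
            self.time_index = {t: i for i, t in enumerate(times)}
            self.T = len(times)
            self.times = times
            self.structure = _STRUCTURES[rep["structure"]](self.T, times)
            self.subject_col = subject
            subj = data[subject].to_numpy()
        else:
            self.T = 1
            self.times = np.array([0.0])
            self.structure = _STRUCTURES["iid"](1, self.times)
            self.subject_col = None
            subj = np.arange(len(data)).astype(str)
        self.data = data
        self.y = np.asarray(data[spec.response], dtype=float)
        self.X, self.builder = build_design(
            data, spec.fixed, spec.ref_levels, set(spec.categorical)
        )
        self.n, self.p = self.X.shape

        random_terms = list(spec.random)
        auto = spec.animal_intercept
        if rep is not None and self.subject_col is not None:
            want = auto == "always" or (
                auto == "auto" and rep["structure"] in ("ar1", "arh1")
            )
            if want and self.subject_col not in random_terms:
                random_terms.append(self.subject_col)
        self.random_terms = random_terms
        rand_labels = [_random_labels(data, t).to_numpy() for t in random_terms]

        # blocks: union-find over subjects sharing any random-effect level
        uniq_subj, subj_idx = np.unique(subj, return_inverse=True)
        parent = list(range(len(uniq_subj)))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for labels in rand_labels:
            first = {}
            for i, lab in enumerate(labels):
                s = subj_idx[i]
                if lab in first:
                    union(first[lab], s)
                else:
                    first[lab] = s
        roots = np.array([find(s) for s in subj_idx])

        if rep is not None:
            tvals = data[rep["time"]].to_numpy()
            tidx = np.array([self.time_index[t] for t in tvals])
        else:
            tidx = np.zeros(len(data), dtype=int)

        self.blocks = []
        self.n_subjects = len(uniq_subj)
        for root in np.unique(roots):
            rows = np.where(roots == root)[0]
            bsubj = subj_idx[rows]
            order = np.lexsort((tidx[rows], bsubj))
            rows = rows[order]
            bsubj = subj_idx[rows]
            btidx = tidx[rows]
            sub_patterns = tuple(
                tuple(btidx[bsubj == s]) for s in pd.unique(bsubj)
            )
            zs, zsig = [], []
            for labels in rand_labels:
                loc = labels[rows]
                uniq, inv = np.unique(loc, return_inverse=True)
                Z = np.zeros((len(rows), len(uniq)))
                Z[np.arange(len(rows)), inv] = 1.0
                zs.append(Z)
                zsig.append(tuple(inv.tolist()))
            # per-subject contiguous spans (rows are sorted by subject, time)
            spans = []
            start = 0
            for s in pd.unique(bsubj):
                cnt = int((bsubj == s).sum())
                spans.append((start, cnt, btidx[start : start + cnt]))
                start += cnt
            self.blocks.append(
                {
                    "rows": rows,
                    "subj": bsubj,
                    "tidx": btidx,
                    "Z": zs,
                    "spans": spans,
                    "Xb": None,  # filled after X is built
                    "yb": None,
                    "key": (sub_patterns, tuple(zsig)),
                }
            )
        for b in self.blocks:
            b["Xb"] = self.X[b["rows"]]
            b["yb"] = self.y[b["rows"]]
        self.n_theta = len(random_terms) + self.structure.n_params

    # -- initial values ------------------------------------------------------

    def init_theta(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        total = float(np.var(resid)) or 1e-6
        S = np.zeros((self.T, self.T))
        cnt = np.zeros((self.T, self.T))
        for b in self.blocks:
            for s in pd.unique(b["subj"]):
                m = b["subj"] == s
                ti = b["tidx"][m]
                r = resid[b["rows"][m]]
                S[np.ix_(ti, ti)] += np.outer(r, r)
                cnt[np.ix_(ti, ti)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(cnt > 0, S / np.maximum(cnt, 1), 0.0)
        if not np.all(np.isfinite(S)) or np.all(S == 0):
            S = total * np.eye(self.T)
        d = np.diag(S).copy()
        d[d <= 1e-10] = total
        S = S.copy()
        np.fill_diagonal(S, d)
        n_r = len(self.random_terms)
        if n_r:
            share = 0.2 * total
            S_res = S - share * np.ones_like(S)
            np.fill_diagonal(S_res, np.diag(S) - 0.5 * share)
            ev = np.linalg.eigvalsh((S_res + S_res.T) / 2)
            if ev[0] <= 1e-8:
                S_res = 0.8 * S
            theta_r = np.full(n_r, np.log(max(share, 1e-8)))
            return np.concatenate([theta_r, self.structure.init(S_res)])
        return self.structure.init(S)

    # -- REML objective ------------------------------------------------------

    def minus2_reml(self, theta: np.ndarray) -> float:
        n_r = len(self.random_terms)
        rvar = np.exp(theta[:n_r]) + _VAR_FLOOR if n_r else np.zeros(0)
        R = self.structure.build(np.asarray(theta[n_r:], dtype=float))
        if R is None:
            return _BIG
        logdet_v = 0.0
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        ytViy = 0.0
        cache = {}
        try:
            for b in self.blocks:
                key = b["key"]
                fac = cache.get(key)
                if fac is None:
                    V = self._block_v(b, R, rvar)
                    c, low = cho_factor(V, lower=True)
                    ld = 2.0 * float(np.sum(np.log(np.diag(c))))
                    fac = ((c, low), ld)
                    cache[key] = fac
                (c, low), ld = fac
                logdet_v += ld
                Xb, yb = b["Xb"], b["yb"]
                A = cho_solve((c, low), np.column_stack([Xb, yb]))
                XtViX += Xb.T @ A[:, :-1]
                XtViy += Xb.T @ A[:, -1]
                ytViy += float(yb @ A[:, -1])
            cx, lowx = cho_factor(XtViX)
            beta = cho_solve((cx, lowx), XtViy)
            logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx))))
            quad = ytViy - float(beta @ XtViy)
        except (np.linalg.LinAlgError, ValueError):
            return _BIG
        if not np.isfinite(quad) or quad < -1e-6:
            return _BIG
        return logdet_v + logdet_x + max(quad, 0.0) + (self.n - self.p) * _LOG2PI

    def _block_v(self, b, R, rvar):
        m = len(b["rows"])
        V = np.zeros((m, m))
        for start, cnt, ti in b["spans"]:
            V[start : start + cnt, start : start + cnt] = R[np.ix_(ti, ti)]
        for v, Z in zip(rvar, b["Z"]):
            V += v * (Z @ Z.T)
        return V

    def gls_at(self, theta: np.ndarray):
        """(beta, cov(beta), R, random variances) at unconstrained params."""
        n_r = len(self.random_terms)
        rvar = np.exp(theta[:n_r]) + _VAR_FLOOR if n_r else np.zeros(0)
        R = self.structure.build(np.asarray(theta[n_r:], dtype=float))
        if R is None:
            raise LmmError("non-PD covariance at solution")
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        for b in self.blocks:
            V = self._block_v(b, R, rvar)
            c = cho_factor(V, lower=True)
            Xb = b["Xb"]
            A = cho_solve(c, np.column_stack([Xb, b["yb"]]))
            XtViX += Xb.T @ A[:, :-1]
            XtViy += Xb.T @ A[:, -1]
        cov = np.linalg.inv(XtViX)
        beta = cov @ XtViy
        return beta, cov, R, rvar


def build_problem(spec: ModelSpec, data: pd.DataFrame) -> _Problem:
    """Prepare (and expose, mainly for testing) the REML problem."""
    return _Problem(spec, data)


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class LmmFit:
    spec: ModelSpec
    structure: str
    theta: np.ndarray
    params: dict
    random_variances: dict
    beta: np.ndarray
    fe_names: list
    fe_vcov: np.ndarray
    residual_cov: np.ndarray
    times: np.ndarray
    loglik: float
    aic: float
    aicc: float
    bic: float
    n_cov_params: int
    converged: bool
    n_obs: int
    rank_x: int
    n_subjects: int
    builder: DesignBuilder
    term_tests: pd.DataFrame

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.rank_x

    def fe_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.fe_vcov))
        t = np.where(se > 0, self.beta / np.where(se > 0, se, 1.0), np.nan)
        p = 2 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(
            {"effect": self.fe_names, "estimate": self.beta, "se": se, "t": t, "p": p}
        )


def fit_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 2,
) -> LmmFit:
    """Maximise the REML log-likelihood and return the fitted model.

    Quasi-Newton optimisation from a data-driven start plus ``n_restarts``
    seeded jittered restarts, followed by a derivative-free polish; the best
    optimum is kept.  A fit that never reports optimiser success is flagged
    ``converged=False`` (model selection skips such fits).
    """
    prob = _Problem(spec, data)
    rng = np.random.default_rng(seed)
    theta0 = prob.init_theta()
    # restarts and the derivative-free polish pay off for low-dimensional
    # structures; for UN-sized parameter vectors the data-driven start is
    # close and one quasi-Newton run suffices
    small = prob.n_theta <= 8
    starts = [theta0]
    if small:
        for _ in range(n_restarts):
            starts.append(theta0 + rng.normal(0.0, 0.4, size=len(theta0)))
    best, best_ok = None, False
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                prob.minus2_reml, s, method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
        if best is None or res.fun < best.fun - 1e-9:
            best, best_ok = res, bool(res.success)
        elif abs(res.fun - best.fun) <= 1e-9 and res.success:
            best_ok = True
    if best.fun >= _BIG / 2:
        raise LmmError("REML objective not finite at any start")
    if not best_ok:
        # restarting L-BFGS-B resets its Hessian memory, which usually
        # finishes off a stalled high-dimensional run
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                prob.minus2_reml, best.x, method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
        if res.fun <= best.fun:
            best, best_ok = res, bool(res.success)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pol = optimize.minimize(
            prob.minus2_reml, best.x, method="Nelder-Mead",
            options={
                "maxiter": (400 if small else 40) * len(best.x),
                "xatol": 1e-9, "fatol": 1e-11,
            },
        )
    if pol.fun < best.fun:
        best = pol
        best_ok = best_ok or bool(pol.success)
    if not best_ok:
        # accept a stationary point: relative gradient small
        g = optimize.approx_fprime(best.x, prob.minus2_reml, 1e-6)
        best_ok = bool(np.max(np.abs(g)) < 1e-2 * (1.0 + abs(best.fun)))

    theta = np.asarray(best.x, dtype=float)
    m2l = float(best.fun)
    beta, cov, R, rvar = prob.gls_at(theta)
    q = prob.n_theta
    n_eff = prob.n - prob.p
    aic = m2l + 2 * q
    denom = n_eff - q - 1
    aicc = aic + (2 * q * (q + 1) / denom if denom > 0 else np.inf)
    bic = m2l + q * np.log(max(prob.n_subjects, 2))
    n_r = len(prob.random_terms)
    rand_var = {
        t: float(np.exp(theta[i]))
        for i, t in enumerate(prob.random_terms)
    }
    fit = LmmFit(
        spec=spec,
        structure=prob.structure.kind,
        theta=theta,
        params=prob.structure.describe(np.asarray(theta[n_r:])),
        random_variances=rand_var,
        beta=beta,
        fe_names=prob.builder.colnames,
        fe_vcov=cov,
        residual_cov=R,
        times=prob.times,
        loglik=-0.5 * m2l,
        aic=aic,
        aicc=aicc,
        bic=bic,
        n_cov_params=q,
        converged=best_ok,
        n_obs=prob.n,
        rank_x=prob.p,
        n_subjects=prob.n_subjects,
        builder=prob.builder,
        term_tests=pd.DataFrame(),
    )
    fit.term_tests = _term_tests(fit)
    return fit


def _term_tests(fit: LmmFit) -> pd.DataFrame:
    """Wald F test for each fixed term (residual denominator df)."""
    rows = []
    df2 = fit.df_resid
    for term, idx in fit.builder.term_index.items():
        if not idx:
            rows.append({"term": term, "f": np.nan, "df1": 0, "df2": df2, "p": np.nan})
            continue
        b = fit.beta[idx]
        C = fit.fe_vcov[np.ix_(idx, idx)]
        try:
            F = float(b @ np.linalg.solve(C, b)) / len(idx)
        except np.linalg.LinAlgError:
            F = np.nan
        p = float(stats.f.sf(F, len(idx), df2)) if np.isfinite(F) else np.nan
        rows.append({"term": term, "f": F, "df1": len(idx), "df2": df2, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model selection, pruning
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    fits: dict
    ranking: pd.DataFrame
    chosen: str
    lrt: dict | None


def select_structure(
    spec: ModelSpec,
    data: pd.DataFrame,
    candidates: list,
    seed: int = 0,
) -> SelectionResult:
    """Fit candidate covariance structures, rank by AICc, LRT the top two.

    The two best-fitting converged structures are compared by a REML
    likelihood-ratio chi-square (df = difference in covariance-parameter
    count) when their marginal covariance families are nested; the simpler
    structure wins at p >= 0.05.
    """
    fits = {}
    for i, kind in enumerate(candidates):
        try:
            f = fit_lmm(spec.with_structure(kind), data, seed=seed + i)
        except LmmError:
            continue
        if f.converged:
            fits[kind] = f
    if not fits:
        raise LmmError("no candidate covariance structure converged")
    ranking = pd.DataFrame(
        [
            {
                "structure": k, "loglik": f.loglik, "q": f.n_cov_params,
                "aic": f.aic, "aicc": f.aicc, "bic": f.bic,
            }
            for k, f in fits.items()
        ]
    ).sort_values("aicc").reset_index(drop=True)
    chosen = ranking.loc[0, "structure"]
    lrt = None
    if len(ranking) >= 2:
        k1, k2 = ranking.loc[0, "structure"], ranking.loc[1, "structure"]
        simple = complx = None
        if k1 in _NESTED_IN.get(k2, set()):
            simple, complx = k1, k2
        elif k2 in _NESTED_IN.get(k1, set()):
            simple, complx = k2, k1
        if simple is not None:
            fs, fc = fits[simple], fits[complx]
            stat = max(0.0, 2.0 * (fc.loglik - fs.loglik))
            df = max(fc.n_cov_params - fs.n_cov_params, 1)
            p = float(stats.chi2.sf(stat, df))
            lrt = {"simple": simple, "complex": complx, "stat": stat, "df": df, "p": p}
            chosen = simple if p >= 0.05 else complx
    return SelectionResult(fits=fits, ranking=ranking, chosen=chosen, lrt=lrt)


def prune_interactions(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.10,
    seed: int = 0,
) -> tuple:
    """Drop interaction terms one at a time until all remaining beat alpha.

    At each step the single interaction with the largest Wald p >= alpha is
    removed and the model refitted; main effects are never dropped.  An
    ``alpha`` of 1 (or more) removes every interaction.  Returns
    ``(final_spec, fit, trail)``.
    """
    cur = spec
    trail = []
    step = 0
    while True:
        fit = fit_lmm(cur, data, seed=seed)
        tt = fit.term_tests
        inter = tt[tt["term"].astype(str).str.contains(r"\*")]
        if alpha >= 1.0:
            cand = inter
        else:
            cand = inter[inter["p"].isna() | (inter["p"] >= alpha)]
        if cand.empty:
            for _, r in inter.iterrows():
                trail.append(
                    {"step": step, "term": r["term"], "p": r["p"], "action": "kept"}
                )
            return cur, fit, pd.DataFrame(trail)
        victim = cand.sort_values("p", na_position="last").iloc[-1]
        trail.append(
            {"step": step, "term": victim["term"], "p": victim["p"], "action": "dropped"}
        )
        cur = replace(cur, fixed=[t for t in cur.fixed if t != victim["term"]])
        step += 1


# ---------------------------------------------------------------------------
# LS means
# ---------------------------------------------------------------------------


@dataclass
class LSMeansTable:
    factor: tuple
    table: pd.DataFrame
    pairwise: pd.DataFrame


def _letters(levels: list, sig: dict) -> dict:
    """Compact letter display from pairwise significance (insert/absorb)."""
    groups = [set(levels)]
    for (a, b), is_sig in sig.items():
        if not is_sig:
            continue
        new = []
        for g in groups:
            if a in g and b in g:
                new.append(g - {b})
                new.append(g - {a})
            else:
                new.append(g)
        # absorb subsets
        pruned = []
        for h in new:
            if not any(h < other or (h == other and other is not h and other in pruned) for other in new):
                pruned.append(h)
        # dedupe
        groups = []
        for h in pruned:
            if h and h not in groups:
                groups.append(h)
    groups.sort(key=lambda g: min(levels.index(l) for l in g))
    out = {l: "" for l in levels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, g in enumerate(groups):
        for l in levels:
            if l in g:
                out[l] += alphabet[i % len(alphabet)]
    return out


def ls_means(fit: LmmFit, factor, alpha: float = 0.05) -> LSMeansTable:
    """Model-adjusted marginal means of ``factor`` (str or tuple of str).

    Other factors are averaged with equal weight over their observed valid
    combinations; covariates sit at their training means.  SEs come from the
    fixed-effect covariance; pairwise comparisons are Wald t tests with
    residual df, summarised by letter groupings at ``alpha``.
    """
    if isinstance(factor, str):
        factor = (factor,)
    b = fit.builder
    for fvar in factor:
        if fvar not in b.categorical_vars:
            raise LmmError(f"{fvar!r} is not a categorical term in the model")
    combos = b.observed_combos.copy()
    if combos.empty:
        raise LmmError("model has no categorical terms")
    level_sets = [b.categorical_vars[f] for f in factor]
    rows, lvecs = [], {}
    for combo in itertools.product(*level_sets):
        m = np.ones(len(combos), dtype=bool)
        for fvar, lev in zip(factor, combo):
            m &= combos[fvar].to_numpy() == lev
        sub = combos[m]
        if sub.empty:
            warnings.warn(
                f"no observed cells for {dict(zip(factor, combo))}; LS mean "
                "not estimable",
                stacklevel=2,
            )
            rows.append({"level": combo, "estimate": np.nan, "se": np.nan})
            continue
        grid = sub.copy()
        for cov, mean in b.covariate_means.items():
            grid[cov] = mean
        Xg = b.build(grid)
        ell = Xg.mean(axis=0)
        lvecs[combo] = ell
        rows.append(
            {
                "level": combo,
                "estimate": float(ell @ fit.beta),
                "se": float(np.sqrt(ell @ fit.fe_vcov @ ell)),
            }
        )
    df = fit.df_resid
    table = pd.DataFrame(rows)
    table["df"] = df
    prs, sig = [], {}
    keys = list(lvecs)
    for a, c in itertools.combinations(keys, 2):
        d = lvecs[a] - lvecs[c]
        diff = float(d @ fit.beta)
        se = float(np.sqrt(d @ fit.fe_vcov @ d))
        t = diff / se if se > 0 else np.nan
        p = 2 * float(stats.t.sf(abs(t), df)) if np.isfinite(t) else np.nan
        prs.append({"a": a, "b": c, "diff": diff, "se": se, "t": t, "p": p})
        sig[(a, c)] = bool(np.isfinite(p) and p < alpha)
    letters = _letters(keys, sig) if keys else {}
    table["letters"] = [letters.get(l, "") for l in table["level"]]
    return LSMeansTable(factor=factor, table=table, pairwise=pd.DataFrame(prs))


# ---------------------------------------------------------------------------
# FCE-on-BWG slopes
# ---------------------------------------------------------------------------


def fce_bwg_slopes(phenotypes: pd.DataFrame) -> dict:
    """Per-climate OLS slope of FCE on BWG and the TN-vs-HS slope contrast.

    Faster-growing pigs dilute maintenance requirements and convert feed
    more efficiently; the slope of that relationship is compared between
    climates.  Requires at least 3 rows with defined FCE per climate.
    """
    out = {}
    for clim, g in phenotypes.groupby("climate"):
        g = g.dropna(subset=["fce", "bwg_kgd"])
        if len(g) < 3:
            raise LmmError(f"fewer than 3 usable rows in climate {clim}")
        x = np.asarray(g["bwg_kgd"], float)
        y = np.asarray(g["fce"], float)
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / (len(x) - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        out[clim] = {
            "slope": float(beta[1]),
            "se": float(np.sqrt(cov[1, 1])),
            "intercept": float(beta[0]),
            "n": int(len(x)),
        }
    if "TN" in out and "HS" in out:
        d = out["HS"]["slope"] - out["TN"]["slope"]
        se = float(np.hypot(out["HS"]["se"], out["TN"]["se"]))
        z = d / se if se > 0 else np.nan
        out["contrast"] = {
            "hs_minus_tn": d,
            "se": se,
            "z": z,
            "p": 2 * float(stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        }
    return out
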