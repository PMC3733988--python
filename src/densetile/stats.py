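"""Repeatability, group comparisons and mixed-model intensity analysis.

Repeatability of replicated probe signals is the intraclass correlation
r = S_A^2 / (S^2 + S_A^2), where S_A^2 is the between-probe variance
component and S^2 the within-probe variance, estimated from a one-way
ANOVA decomposition with the standard unbalanced-design correction
n0 = (N - sum n_i^2 / N) / (k - 1).

The intensity models regress log_e median signal on probe sequence
covariates (GC%, log off-target count, free energy, homopolymer run
lengths), the feature background (log_e), and design-geometry
covariates (tiling offset as a factor; log_e segment length; then,
depending on the preset, probe position within the segment, log_e
distance across the adjacent masked gap, or the class and log_e
combined length of the adjacent repeats).  Probe, dog and DNA source
enter as random effects; the homopolymer covariates additionally get
regression-spline terms to capture their non-linear influence.  Fitting
is by REML through a linear mixed model with a random probe intercept;
an ordinary-least-squares mode with probe-clustered robust standard
errors serves as a documented fallback when REML does not converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .qc import IntensityMatrix

# ---------------------------------------------------------------------------
# repeatability


@dataclass
class RepeatabilityResult:
    """Intraclass-correlation repeatability of grouped observations."""

    r: float
    s2_between: float
    s2_within: float
    n_groups: int
    n_total: int
    n0: float
    s2_between_raw: float  # before truncation at zero
    degenerate: bool = False  # all observations identical


def repeatability(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> RepeatabilityResult:
    """Repeatability r = S_A^2 / (S^2 + S_A^2) from replicate groups.

    ``groups`` maps group label -> observations (or is a plain sequence
    of groups).  Requires at least two groups and at least one residual
    degree of freedom.  A negative between-group variance estimate is
    truncated to zero (the raw value is retained in the result); if
    every observation is identical the decomposition is degenerate and
    r is defined as 1 with the degenerate flag set.
    """
    if isinstance(groups, Mapping):
        gs = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        gs = [np.asarray(v, dtype=float) for v in groups]
    if len(gs) < 2:
        raise ValueError("repeatability needs at least two groups")
    if any(len(g) < 1 for g in gs):
        raise ValueError("every group needs at least one observation")
    sizes = np.array([len(g) for g in gs], dtype=float)
    n_total = int(sizes.sum())
    k = len(gs)
    if n_total - k < 1:
        raise ValueError("no residual degrees of freedom (need replicates)")

    allvals = np.concatenate(gs)
    grand = allvals.mean()
    means = np.array([g.mean() for g in gs])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(gs, means)))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - float(np.sum(sizes**2)) / n_total) / (k - 1)
    s2_between_raw = (ms_between - ms_within) / n0
    s2_between = max(0.0, s2_between_raw)
    denom = ms_within + s2_between

    if denom == 0.0:
        return RepeatabilityResult(
            r=1.0,
            s2_between=0.0,
            s2_within=0.0,
            n_groups=k,
            n_total=n_total,
            n0=n0,
            s2_between_raw=s2_between_raw,
            degenerate=True,
        )
    return RepeatabilityResult(
        r=s2_between / denom,
        s2_between=s2_between,
        s2_within=ms_within,
        n_groups=k,
        n_total=n_total,
        n0=n0,
        s2_between_raw=s2_between_raw,
    )


def replicate_groups(matrix: IntensityMatrix, array_id: str) -> dict[str, list[float]]:
    """Group replicated feature signals by parent probe for one array.

    Replicate copies carry ids ``<probe_id>#<k>``; the parent probe's
    own feature keeps the plain id.  Only probes with at least two
    copies on the array are returned.
    """
    col = matrix.signal[array_id]
    groups: dict[str, list[float]] = {}
    for pid, value in col.items():
        if pd.isna(value):
            continue
        parent = pid.split("#", 1)[0]
        groups.setdefault(parent, []).append(float(value))
    return {k: v for k, v in groups.items() if len(v) >= 2}


# ---------------------------------------------------------------------------
# descriptive statistics and group comparison


def coefficient_of_variation(values: Sequence[float], ddof: int = 1) -> float:
    """100 * sample standard deviation / mean (mean must be positive)."""
    arr = np.asarray(values, dtype=float)
    m = arr.mean()
    if m <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(100.0 * arr.std(ddof=ddof) / m)


@dataclass
class GroupComparison:
    """Welch two-sample comparison plus the variance-ratio F test."""

    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    f_ratio: float
    f_df: tuple[int, int]
    f_p: float
    cv_a: float
    cv_b: float


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Unequal-variance t test with Satterthwaite degrees of freedom.

    Also reports the two-sided variance-ratio F test that motivates
    estimating the variances separately, and each group's coefficient
    of variation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance; t test undefined")
    sa2, sb2 = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (len(a) - 1) + sb2**2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)

    if vb == 0:
        f_ratio, f_df, f_p = np.inf, (len(a) - 1, len(b) - 1), 0.0
    else:
        f_ratio = va / vb
        f_df = (len(a) - 1, len(b) - 1)
        cdf = sps.f.cdf(f_ratio, *f_df)
        f_p = 2.0 * min(cdf, 1.0 - cdf)

    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        df=float(df),
        p=float(p),
        f_ratio=float(f_ratio),
        f_df=f_df,
        f_p=float(f_p),
        cv_a=coefficient_of_variation(a) if a.mean() > 0 else float("nan"),
        cv_b=coefficient_of_variation(b) if b.mean() > 0 else float("nan"),
    )


# ---------------------------------------------------------------------------
# model specification and feature tables

PRESETS = ("position", "distance", "repeat")

_BASE_COVARIATES = [
    "probe_gc",
    "log_off_targets",
    "free_energy",
    "poly_a",
    "poly_c",
    "poly_g",
    "poly_t",
    "log_background",
]
SPLINE_VARS = ("poly_a", "poly_c", "poly_g", "poly_t")


@dataclass
class ModelSpec:
    """Term structure of one intensity model preset.

    Exactly one of position / log-distance / log-repeat-length appears
    per preset; the repeat preset adds the repeat class factor and
    drops the off-target covariate (and segment length).
    """

    preset: str
    covariates: list[str]
    factors: list[str]
    spline_vars: tuple[str, ...] = SPLINE_VARS
    random_effects: tuple[str, ...] = ("probe", "dog", "dna_source")
    response: str = "log_intensity"

    @classmethod
    def for_preset(cls, preset: str) -> "ModelSpec":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
        if preset == "position":
            cov = _BASE_COVARIATES + ["log_segment_length", "position"]
            fac = ["offset"]
        elif preset == "distance":
            cov = _BASE_COVARIATES + ["log_segment_length", "log_distance"]
            fac = ["offset"]
        else:  # repeat
            cov = [c for c in _BASE_COVARIATES if c != "log_off_targets"] + ["log_repeat_length"]
            fac = ["repeat_class", "offset"]
        return cls(preset=preset, covariates=cov, factors=fac)


def build_feature_table(
    probes: pd.DataFrame,
    features: pd.DataFrame,
    matrix: IntensityMatrix | pd.DataFrame,
    samples: pd.DataFrame | Iterable,
    preset: str = "position",
    repeat_probes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per probe-array with the preset's model columns.

    ``probes`` carries design geometry (``ProbeSet.to_dataframe()``),
    ``features`` the sequence covariates, ``matrix`` the filtered
    intensities (or an equivalent long DataFrame with probe_id,
    array_id, raw_signal, background), and ``samples`` the array sheet.
    Transforms follow the models: log_e intensity and background,
    log_e segment length, log_e distance, log_e(1 + off-target count),
    log_e repeat length.  The ``distance`` preset keeps only segment-
    edge probes with a positive distance; the ``repeat`` preset keeps
    only the repeat-adjacent subset (``repeat_probes`` from
    ``select_repeat_adjacent_probes``) and drops the off-target
    covariate.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    if preset == "repeat" and repeat_probes is None:
        raise ValueError("repeat preset requires the repeat-adjacent probe subset")

    if isinstance(matrix, IntensityMatrix):
        long = matrix.to_long(include_replicates=False)
    else:
        long = matrix.copy()
    long = long.dropna(subset=["raw_signal"])

    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(
            [
                {"array_id": s.array_id, "dog_id": s.dog_id, "dna_source": s.dna_source}
                for s in samples
            ]
        )

    geom_cols = ["probe_id", "offset", "segment_id", "segment_length", "position"]
    if "distance" in probes.columns:
        geom_cols += ["distance", "is_edge_5p", "is_edge_3p"]
    table = long.merge(probes[geom_cols], on="probe_id", how="inner")
    table = table.merge(features, on="probe_id", how="inner")
    table = table.merge(samples, on="array_id", how="left")

    if (table["raw_signal"] <= 0).any():
        raise ValueError("non-positive raw signal in feature table")
    if (table["background"] <= 0).any():
        raise ValueError("non-positive background in feature table")
    table["log_intensity"] = np.log(table["raw_signal"])
    table["log_background"] = np.log(table["background"])
    table["log_segment_length"] = np.log(table["segment_length"])
    table["log_off_targets"] = np.log1p(table["off_target_matches"])
    table = table.rename(columns={"gc_percent": "probe_gc"})

    if preset == "position":
        keep = [
            "probe_id", "array_id", "dog_id", "dna_source", "log_intensity",
            "probe_gc", "log_off_targets", "free_energy",
            "poly_a", "poly_c", "poly_g", "poly_t",
            "log_background", "log_segment_length", "position", "offset",
        ]
        return table[keep].reset_index(drop=True)

    if preset == "distance":
        edge = table[(table["is_edge_5p"] | table["is_edge_3p"]) & (table["distance"] > 0)].copy()
        edge["log_distance"] = np.log(edge["distance"].astype(float))
        keep = [
            "probe_id", "array_id", "dog_id", "dna_source", "log_intensity",
            "probe_gc", "log_off_targets", "free_energy",
            "poly_a", "poly_c", "poly_g", "poly_t",
            "log_background", "log_segment_length", "log_distance", "offset",
        ]
        return edge[keep].reset_index(drop=True)

    # repeat preset
    sub = table.merge(
        repeat_probes[["probe_id", "repeat_class", "repeat_length"]], on="probe_id", how="inner"
    )
    sub["log_repeat_length"] = np.log(sub["repeat_length"].astype(float))
    keep = [
        "probe_id", "array_id", "dog_id", "dna_source", "log_intensity",
        "probe_gc", "free_energy",
        "poly_a", "poly_c", "poly_g", "poly_t",
        "log_background", "log_repeat_length", "repeat_class", "offset",
    ]
    return sub[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class FitResult:
    """Per-term estimates and tests from one intensity model fit.

    ``terms`` has one row per fixed covariate (estimate, se, fstat, p);
    factor levels are reported with the reference level fixed at 0.
    ``spline_tests`` holds the joint Wald chi-square for each
    homopolymer spline basis.  ``method`` records the backend actually
    used ("reml" or "ols"); a fallback fit is flagged.
    """

    terms: pd.DataFrame
    factor_effects: dict[str, dict[str, tuple[float, float]]]
    spline_tests: pd.DataFrame
    variance_components: dict[str, float]
    method: str
    converged: bool
    fell_back: bool
    n_obs: int
    dropped_terms: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "terms": self.terms.to_dict(orient="records"),
            "factor_effects": {
                f: {lvl: list(eff) for lvl, eff in levels.items()}
                for f, levels in self.factor_effects.items()
            },
            "spline_tests": self.spline_tests.to_dict(orient="records"),
            "variance_components": self.variance_components,
            "method": self.method,
            "converged": self.converged,
            "fell_back": self.fell_back,
            "n_obs": self.n_obs,
            "dropped_terms": self.dropped_terms,
        }


def _spline_basis(x: np.ndarray, max_knots: int = 5) -> np.ndarray:
    """Truncated-linear regression-spline basis (x - knot)_+.

    Knots sit at interior quantiles of the distinct covariate values
    (homopolymer lengths are small integers, so the basis stays modest);
    covariates with fewer than three distinct values get no basis.
    """
    uniq = np.unique(x)
    if len(uniq) < 3:
        return np.empty((len(x), 0))
    interior = uniq[1:-1]
    if len(interior) > max_knots:
        qs = np.linspace(0, 1, max_knots + 2)[1:-1]
        knots = np.unique(np.quantile(interior, qs))
    else:
        knots = interior
    return np.maximum(0.0, x[:, None] - knots[None, :])


def _build_design(
    table: pd.DataFrame, spec: ModelSpec, spline_knots: int
) -> tuple[np.ndarray, list[str], dict[str, list[str]], dict[str, list[tuple[str, str]]], list[str]]:
    """Design matrix with intercept, covariates, factor dummies, splines."""
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["intercept"]
    dropped: list[str] = []
    spline_cols: dict[str, list[str]] = {}
    factor_info: dict[str, list[tuple[str, str]]] = {}

    for cov in spec.covariates:
        x = table[cov].to_numpy(dtype=float)
        if np.isnan(x).all():  # e.g. free energy when no ΔG input was given
            dropped.append(cov)
            continue
        if np.isnan(x).any():
            raise ValueError(f"covariate {cov!r} has missing values for some probes")
        if np.allclose(x, x[0]):
            dropped.append(cov)
            continue
        cols.append(x)
        names.append(cov)

    for fac in spec.factors:
        try:
            levels = sorted(table[fac].unique())
        except TypeError:
            levels = sorted(table[fac].unique(), key=str)
        if len(levels) < 2:
            dropped.append(fac)
            continue
        # reference level: smallest offset / first level alphabetically
        ref = levels[0]
        factor_info[fac] = [(str(ref), "")]  # reference marked by empty column name
        for lvl in levels[1:]:
            colname = f"{fac}[{lvl}]"
            cols.append((table[fac] == lvl).to_numpy(dtype=float))
            names.append(colname)
            factor_info[fac].append((str(lvl), colname))

    for var in spec.spline_vars:
        if var not in table.columns or var in dropped:
            continue
        basis = _spline_basis(table[var].to_numpy(dtype=float), max_knots=spline_knots)
        var_cols = []
        for j in range(basis.shape[1]):
            colname = f"s({var})[{j}]"
            cols.append(basis[:, j])
            names.append(colname)
            var_cols.append(colname)
        if var_cols:
            spline_cols[var] = var_cols

    X = np.column_stack(cols)
    # drop collinear columns greedily (earlier columns take precedence),
    # working on the normalized Gram matrix so the scan is O(p^4) not O(n p^3)
    norms = np.sqrt((X**2).sum(axis=0))
    norms[norms == 0] = 1.0
    G = (X / norms).T @ (X / norms)
    keep_idx: list[int] = []
    for j in range(X.shape[1]):
        trial = keep_idx + [j]
        sub = G[np.ix_(trial, trial)]
        if np.linalg.matrix_rank(sub, tol=1e-8) == len(trial):
            keep_idx.append(j)
        elif names[j] != "intercept":
            dropped.append(names[j])
    if len(keep_idx) < X.shape[1]:
        kept_names = [names[j] for j in keep_idx]
        spline_cols = {v: [c for c in cs if c in kept_names] for v, cs in spline_cols.items()}
        spline_cols = {v: cs for v, cs in spline_cols.items() if cs}
        X = X[:, keep_idx]
        names = kept_names
    return X, names, spline_cols, factor_info, dropped


def _reml_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float], bool]:
    """Exact profiled REML for a random-intercept linear mixed model.

    With V = sigma^2 (I + lambda Z Z') for a grouping factor Z, both
    beta and sigma^2 have closed forms given the variance ratio lambda,
    so the REML criterion reduces to a one-dimensional profile that is
    minimized by bounded scalar search.  This stays numerically stable
    at the extreme variance ratios typical of probe-level data (probe
    variance orders of magnitude above residual variance), where
    general-purpose mixed-model optimizers can fail to converge.

    Returns (beta, bse, cov_beta, variance_components, converged).
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    codes, _ = pd.factorize(groups)
    k = codes.max() + 1
    sizes = np.bincount(codes).astype(float)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group column sums of X and y
    S = np.zeros((k, p))
    np.add.at(S, codes, X)
    t = np.bincount(codes, weights=y)

    def profile(log_lam: float) -> float:
        lam = np.exp(log_lam)
        c = lam / (1.0 + lam * sizes)
        A = XtX - (S * c[:, None]).T @ S
        b = Xty - S.T @ (c * t)
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(L.T, np.linalg.solve(L, b))
        yVy = yty - float(c @ t**2)
        rss = yVy - 2.0 * float(beta @ b) + float(beta @ A @ beta)
        if rss <= 0:
            return np.inf
        logdet_V = float(np.sum(np.log1p(lam * sizes)))
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
        return (n - p) * np.log(rss) + logdet_V + logdet_A

    res = minimize_scalar(profile, bounds=(-23.0, 16.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    c = lam / (1.0 + lam * sizes)
    A = XtX - (S * c[:, None]).T @ S
    b = Xty - S.T @ (c * t)
    beta = np.linalg.solve(A, b)
    yVy = yty - float(c @ t**2)
    rss = yVy - 2.0 * float(beta @ b) + float(beta @ A @ beta)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov_beta))
    vc = {"probe": sigma2 * lam, "residual": sigma2}
    return beta, bse, cov_beta, vc, bool(res.success)


def _wald_joint(params: np.ndarray, cov: np.ndarray, idx: list[int]) -> tuple[float, int, float]:
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        chi2 = float(b @ np.linalg.pinv(V) @ b)
    df = len(idx)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec | str = "position",
    method: str = "auto",
    spline_knots: int = 5,
) -> FitResult:
    """Fit one intensity model and return per-term statistics.

    ``method`` selects the backend: ``"reml"`` (the default under
    ``"auto"``) fits the random-probe-intercept mixed model by exact
    profiled REML; ``"mixedlm"`` delegates the same model to
    statsmodels' general MixedLM optimizer (useful as a cross-check at
    moderate variance ratios); ``"ols"`` fits the fixed part only with
    probe-clustered robust standard errors.  ``"auto"`` falls back to
    OLS if the REML profile fails numerically, flagging the fallback in
    the result.  Zero-variance covariates are dropped and listed in
    ``dropped_terms``.
    """
    import statsmodels.api as sm

    if isinstance(spec, str):
        spec = ModelSpec.for_preset(spec)
    if method not in ("auto", "reml", "mixedlm", "ols"):
        raise ValueError(f"unknown method {method!r}")

    y = table[spec.response].to_numpy(dtype=float)
    X, names, spline_cols, factor_info, dropped = _build_design(table, spec, spline_knots)
    groups = table["probe_id"].to_numpy()

    params = bse = cov = None
    variance_components: dict[str, float] = {}
    used = method
    converged = False
    fell_back = False

    if method in ("auto", "reml"):
        try:
            params, bse, cov, variance_components, converged = _reml_random_intercept(
                y, X, groups
            )
        except np.linalg.LinAlgError:
            converged = False
        if not converged:
            params = None
            if method == "reml":
                raise RuntimeError("REML profile did not converge (try method='ols')")
            fell_back = True
        else:
            used = "reml"
    elif method == "mixedlm":
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True, method=["lbfgs", "powell"])
        if not res.converged:
            raise RuntimeError("MixedLM did not converge (try method='reml' or 'ols')")
        params = np.asarray(res.fe_params)
        bse = np.asarray(res.bse_fe)
        cov = np.asarray(res.cov_params())[: len(params), : len(params)]
        variance_components = {
            "probe": float(np.asarray(res.cov_re)[0, 0]),
            "residual": float(res.scale),
        }
        converged = True

    if params is None:
        res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        cov = np.asarray(res.cov_params())
        variance_components = {"residual": float(res.mse_resid)}
        used = "ols"
        converged = True

    name_idx = {n: i for i, n in enumerate(names)}
    rows = []
    for cov_name in spec.covariates:
        if cov_name in name_idx:
            i = name_idx[cov_name]
            est, se = float(params[i]), float(bse[i])
            f = (est / se) ** 2 if se > 0 else float("nan")
            p = float(sps.chi2.sf(f, 1)) if se > 0 else float("nan")
            rows.append({"term": cov_name, "estimate": est, "se": se, "fstat": f, "p": p})
        else:
            rows.append(
                {"term": cov_name, "estimate": np.nan, "se": np.nan, "fstat": np.nan, "p": np.nan}
            )

    factor_effects: dict[str, dict[str, tuple[float, float]]] = {}
    for fac, levels in factor_info.items():
        eff: dict[str, tuple[float, float]] = {}
        contrast_idx = []
        for lvl, colname in levels:
            if colname == "":
                eff[lvl] = (0.0, 0.0)
            elif colname in name_idx:
                i = name_idx[colname]
                eff[lvl] = (float(params[i]), float(bse[i]))
                contrast_idx.append(i)
        factor_effects[fac] = eff
        if contrast_idx:
            chi2, dfn, p = _wald_joint(params, cov, contrast_idx)
            rows.append(
                {
                    "term": fac,
                    "estimate": np.nan,
                    "se": float(np.mean([bse[i] for i in contrast_idx])),
                    "fstat": chi2 / dfn,
                    "p": p,
                }
            )

    spline_rows = []
    for var, colnames in spline_cols.items():
        idx = [name_idx[c] for c in colnames if c in name_idx]
        if not idx:
            continue
        chi2, dfn, p = _wald_joint(params, cov, idx)
        spline_rows.append({"term": f"s({var})", "chi2": chi2, "df": dfn, "p": p})

    return FitResult(
        terms=pd.DataFrame(rows),
        factor_effects=factor_effects,
        spline_tests=pd.DataFrame(spline_rows, columns=["term", "chi2", "df", "p"]),
        variance_components=variance_components,
        method=used,
        converged=converged,
        fell_back=fell_back,
        n_obs=len(y),
        dropped_terms=dropped,
    )
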