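"""Longitudinal models: random-intercept LMM (ML) and negative-binomial GLMM.

Linear mixed model
------------------
The Gaussian model is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_b),  e_ij ~ N(0, s2_e)

fit by maximum likelihood (not REML, matching the full-information ML
language of the analysis it implements). The marginal likelihood is profiled
over the variance ratio lambda = s2_b / s2_e: given lambda, beta is the GLS
solution and s2_e has a closed form, leaving a one-dimensional optimization
of the profiled deviance. Per-participant blocks V_i = I + lambda J are
inverted analytically (Woodbury), so a fit costs one pass of group sums per
lambda evaluation. All available outcome rows enter the likelihood
(available-case ML, unbiased under missing-at-random).

Negative-binomial GLMM
----------------------
Counts use a log-link NB2 model (variance mu + mu^2/theta) with a Gaussian
random intercept. The per-participant marginal likelihood integral is
approximated by the Laplace method: an inner (damped) Newton iteration finds
the mode of the random effect given (beta, s2_b, theta); the outer
quasi-Newton optimizes the Laplace objective over (beta, log s2_b,
log theta). Wald standard errors come from a finite-difference Hessian at
the optimum.

Effect sizes are semi-partial R^2 per fixed-effect term, R^2 = qF/(qF + nu)
with nu from the containment rule, and confidence intervals by parametric
bootstrap. Family-wise error over the model battery is controlled by
Bonferroni.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConvergenceError, DegenerateDataError, ValidationError

__all__ = [
    "ModelSpec",
    "LmmFit",
    "NbFit",
    "preprocess",
    "simple_code",
    "region_dummies",
    "build_design",
    "fit_lmm_ml",
    "fit_lmm",
    "fit_nb_glmm",
    "fit_nb",
    "nb_laplace_loglik",
    "profiled_deviance",
    "partial_r2",
    "bonferroni",
    "missingness_diagnostics",
]

logger = logging.getLogger(__name__)

REGIONS = ("South", "West", "Midwest", "Northeast")
COUNT_OUTLIER_MAX = 500  # self-reported episode counts above this are implausible


# ---------------------------------------------------------------------------
# Preprocessing and coding
# ---------------------------------------------------------------------------

def preprocess(raw: pd.DataFrame, count_columns: tuple[str, ...] = ("binge_count", "vomit_count"),
               count_max: int = COUNT_OUTLIER_MAX) -> tuple[pd.DataFrame, list[dict]]:
    """First-stay filtering, count-outlier flagging, duplicate checks.

    Keeps only each participant's first treatment episode (smallest value of
    the ``episode`` column, if present). Participants with any self-reported
    episode count above ``count_max`` are flagged via ``exclude_from_counts``
    (retained for all non-count analyses). Every exclusion is returned in a
    log of ``{participant_id, rule, detail}`` records.

    Raises on duplicated (participant, episode, timepoint) rows.
    """
    df = raw.copy()
    log: list[dict] = []
    if "episode" not in df.columns:
        df["episode"] = 1
    dup_keys = ["participant_id", "episode", "timepoint"]
    dup = df.duplicated(subset=dup_keys, keep=False)
    if dup.any():
        offenders = df.loc[dup, dup_keys].drop_duplicates().to_dict("records")
        raise ValidationError(f"duplicate participant x timepoint rows: {offenders}")

    first = df.groupby("participant_id")["episode"].transform("min")
    later = df["episode"] != first
    for pid in df.loc[later, "participant_id"].unique():
        log.append({"participant_id": pid, "rule": "first_stay_only",
                    "detail": "dropped later treatment episode rows"})
    df = df[~later].drop(columns="episode")

    flagged = pd.Series(False, index=df.index)
    for col in count_columns:
        if col in df.columns:
            flagged |= df[col] > count_max
    bad_ids = set(df.loc[flagged, "participant_id"])
    df["exclude_from_counts"] = df["participant_id"].isin(bad_ids)
    for pid in sorted(bad_ids):
        log.append({"participant_id": pid, "rule": "count_outlier",
                    "detail": f"episode count > {count_max}; removed from count models"})
    for entry in log:
        logger.info("preprocess exclusion: %s", entry)
    return df.reset_index(drop=True), log


def simple_code(values: pd.Series | np.ndarray, levels: list[str],
                reference: str) -> pd.DataFrame:
    """Simple-coded contrast columns for a categorical predictor.

    One column per non-reference level; rows of that level get (k-1)/k and
    all other rows -1/k. Coefficients are level-vs-reference mean
    differences while the intercept is the unweighted grand mean of level
    means.
    """
    values = pd.Series(values)
    if reference not in levels:
        raise ValidationError(f"reference {reference!r} not among levels {levels}")
    unknown = set(values.dropna()) - set(levels)
    if unknown:
        raise ValidationError(f"unknown levels {sorted(unknown)}")
    k = len(levels)
    if k < 2:
        raise ValidationError("simple coding needs >= 2 levels")
    out = {}
    missing = values.isna().to_numpy()
    for lev in levels:
        if lev == reference:
            continue
        col = np.where(values == lev, (k - 1) / k, -1 / k)
        out[f"{lev}_vs_{reference}"] = np.where(missing, np.nan, col)
    return pd.DataFrame(out, index=values.index)


def region_dummies(values: pd.Series | np.ndarray, reference: str = "South",
                   levels: tuple[str, ...] = REGIONS) -> pd.DataFrame:
    """0/1 indicator columns for each non-reference region."""
    values = pd.Series(values)
    unknown = set(values.dropna()) - set(levels)
    if unknown:
        raise ValidationError(f"unknown region levels {sorted(unknown)}")
    return pd.DataFrame(
        {f"region_{lev}": (values == lev).astype(float)
         for lev in levels if lev != reference},
        index=values.index,
    )


def bonferroni(alpha_family: float = 0.05, m_tests: int = 1) -> float:
    """Per-test significance threshold alpha / m (full precision)."""
    if m_tests < 1:
        raise ValidationError("m_tests must be >= 1")
    return alpha_family / m_tests


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Specification of one longitudinal model.

    ``predictors`` are term names resolved against the dataset columns
    (``diagnosis`` expands to simple-coded contrasts, ``region`` and ``loc``
    to indicator dummies; anything else must be a numeric column).
    ``interactions`` lists predictor terms crossed with time; their main
    effects are added automatically, so every interaction's main effect is
    always present.
    """

    outcome: str
    predictors: tuple[str, ...] = ("time", "age", "los")
    interactions: tuple[str, ...] = ()
    family: str = "gaussian"
    diagnosis_reference: str = "AN"
    diagnosis_levels: tuple[str, ...] = ("AN", "BN", "BED", "OSFED_UFED")
    region_reference: str = "South"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "negbin"):
            raise ValidationError(f"unknown family {self.family!r}")

    @property
    def label(self) -> str:
        return self.name or f"{self.outcome}_{self.family}"


_COLUMN_MAP = {"time": "time_days", "age": "age_admission", "los": "los_total"}


def _term_columns(df: pd.DataFrame, term: str, spec: ModelSpec) -> pd.DataFrame:
    if term == "diagnosis":
        return simple_code(df["diagnosis4"], list(spec.diagnosis_levels),
                           spec.diagnosis_reference)
    if term == "diagnosis_counts":
        # count models: AN-BP as reference among binge/purge diagnoses; other
        # diagnoses code as NaN and drop with their missing count outcome
        levels = [lev for lev in ("AN-BP", "BN", "BED")
                  if (df["diagnosis"] == lev).any()]
        masked = df["diagnosis"].where(df["diagnosis"].isin(levels))
        return simple_code(masked, levels, "AN-BP")
    if term == "region":
        return region_dummies(df["region"], spec.region_reference)
    if term == "loc":
        dummies = pd.get_dummies(df["loc_admit"], prefix="loc").astype(float)
        ref = "loc_RES" if "loc_RES" in dummies else dummies.columns[0]
        return dummies.drop(columns=ref)
    col = _COLUMN_MAP.get(term, term)
    if col not in df.columns:
        raise ValidationError(f"term {term!r}: column {col!r} not in data")
    return df[[col]].rename(columns={col: term}).astype(float)


@dataclass
class DesignInfo:
    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray  # integer codes 0..G-1
    colnames: list[str]
    terms: dict[str, list[int]]
    index: pd.Index


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Assemble outcome, fixed-effect design and grouping for a ModelSpec.

    Rows with a missing outcome or any missing covariate are dropped
    (available-case analysis). Raises if the resulting design is rank
    deficient.
    """
    blocks: dict[str, pd.DataFrame] = {}
    for term in spec.predictors:
        blocks[term] = _term_columns(data, term, spec)
    time_col = data[_COLUMN_MAP["time"]].astype(float)
    for term in spec.interactions:
        if term not in blocks:  # interaction main effect always included
            blocks[term] = _term_columns(data, term, spec)
    for term in spec.interactions:
        inter = blocks[term].mul(time_col, axis=0)
        inter.columns = [f"time_x_{c}" for c in blocks[term].columns]
        blocks[f"time_x_{term}"] = inter

    design = pd.concat(blocks.values(), axis=1)
    terms: dict[str, list[int]] = {"intercept": [0]}
    colnames = ["intercept"]
    pos = 1
    for term, blk in blocks.items():
        terms[term] = list(range(pos, pos + blk.shape[1]))
        colnames.extend(blk.columns)
        pos += blk.shape[1]

    y = pd.to_numeric(data[spec.outcome], errors="coerce")
    keep = y.notna() & design.notna().all(axis=1)
    if "exclude_from_counts" in data.columns and spec.family == "negbin":
        keep &= ~data["exclude_from_counts"].astype(bool)
    y = y[keep].to_numpy(dtype=float)
    X = np.column_stack([np.ones(keep.sum()), design[keep].to_numpy(dtype=float)])
    groups, _ = pd.factorize(data.loc[keep, "participant_id"], sort=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"design matrix for {spec.label} is rank deficient")
    return DesignInfo(y=y, X=X, groups=np.asarray(groups), colnames=colnames,
                      terms=terms, index=data.index[keep])


# ---------------------------------------------------------------------------
# Linear mixed model by profiled maximum likelihood
# ---------------------------------------------------------------------------

class _ProfileData:
    """Precomputed sufficient statistics for profiled-ML fits.

    Caches the X-side quantities so repeated fits with new outcome vectors
    (parametric bootstrap) only recompute the y-side sums.
    """

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.order = order
        self.X = X[order]
        self.groups = groups[order]
        self.n_obs, self.p = X.shape
        self.group_ids, self.n_i = np.unique(self.groups, return_counts=True)
        self.n_groups = len(self.group_ids)
        self.codes = np.searchsorted(self.group_ids, self.groups)
        self.XtX = self.X.T @ self.X
        # per-group column sums of X: G x p
        self.Sx = np.zeros((self.n_groups, self.p))
        np.add.at(self.Sx, self.codes, self.X)

    def y_stats(self, y: np.ndarray) -> dict:
        y = y[self.order] if y.shape[0] == self.n_obs else y
        Sy = np.bincount(self.codes, weights=y, minlength=self.n_groups)
        return {"y": y, "Xty": self.X.T @ y, "yty": float(y @ y), "Sy": Sy}

    def deviance(self, lam: float, ys: dict) -> tuple[float, np.ndarray, float, np.ndarray]:
        """-2 log-likelihood profiled over beta and s2_e at fixed lambda."""
        w = lam / (1.0 + lam * self.n_i)  # Woodbury weight per group
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        bvec = ys["Xty"] - self.Sx.T @ (w * ys["Sy"])
        c = ys["yty"] - float(w @ ys["Sy"] ** 2)
        try:
            beta = np.linalg.solve(A, bvec)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise DegenerateDataError("GLS system singular") from exc
        rss = c - float(beta @ bvec)
        if rss <= 0:
            raise DegenerateDataError("non-positive profiled residual variance")
        s2e = rss / self.n_obs
        dev = (self.n_obs * np.log(2.0 * np.pi * s2e)
               + float(np.log1p(lam * self.n_i).sum()) + self.n_obs)
        return dev, beta, s2e, A


def profiled_deviance(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                      lam: float) -> float:
    """Profiled -2 log-likelihood at variance ratio ``lam`` (for diagnostics)."""
    pd_ = _ProfileData(np.asarray(X, float), np.asarray(groups))
    ys = pd_.y_stats(np.asarray(y, float))
    return pd_.deviance(lam, ys)[0]


@dataclass
class LmmFit:
    """Fitted random-intercept linear mixed model (ML)."""

    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma2_b: float
    sigma2_e: float
    lambda_: float
    loglik: float
    n_obs: int
    n_groups: int
    boundary: bool
    converged: bool
    cov_params: np.ndarray
    terms: dict[str, list[int]] = field(default_factory=dict)
    _profile: _ProfileData | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"est": self.params, "se": self.se,
                             "z": self.zvalues, "p": self.pvalues})


def _fit_profiled(prof: _ProfileData, y: np.ndarray,
                  lambda_fixed: float | None = None,
                  tol: float = 1e-10) -> tuple[float, np.ndarray, float, np.ndarray, float, bool]:
    ys = prof.y_stats(y)
    if lambda_fixed is not None:
        lam = float(lambda_fixed)
    else:
        obj = lambda u: prof.deviance(np.exp(u), ys)[0]
        res = optimize.minimize_scalar(obj, bounds=(-14.0, 14.0), method="bounded",
                                       options={"xatol": 1e-10})
        if not res.success:  # pragma: no cover
            raise ConvergenceError(f"profiled-deviance optimization failed: {res}")
        lam = float(np.exp(res.x))
        # the boundary s2_b = 0 is outside the log parameterization; accept it
        # whenever it does at least as well (up to the convergence tolerance)
        dev0 = prof.deviance(0.0, ys)[0]
        if dev0 <= res.fun + tol * max(1.0, abs(res.fun)):
            lam = 0.0
    dev, beta, s2e, A = prof.deviance(lam, ys)
    boundary = lam == 0.0
    return lam, beta, s2e, A, dev, boundary


def fit_lmm_ml(y, X, groups, colnames: list[str] | None = None,
               terms: dict[str, list[int]] | None = None,
               lambda_fixed: float | None = None) -> LmmFit:
    """Fit the random-intercept LMM by profiled maximum likelihood.

    ``groups`` is any array of participant labels; ``lambda_fixed`` pins the
    variance ratio (0 reduces the fit to OLS). Wald z statistics and
    two-sided normal p-values are reported per coefficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(pd.factorize(np.asarray(groups))[0])
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValidationError("y and X have incompatible shapes")
    if len(np.unique(groups)) < 2:
        raise ValidationError("need >= 2 participants")
    prof = _ProfileData(X, groups)
    lam, beta, s2e, A, dev, boundary = _fit_profiled(prof, y, lambda_fixed)
    if boundary:
        logger.info("random-intercept variance hit the boundary sigma2_b = 0")
    cov = s2e * np.linalg.inv(A)
    names = colnames or [f"x{i}" for i in range(X.shape[1])]
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(names)
    return LmmFit(
        params=pd.Series(beta, index=idx), se=pd.Series(se, index=idx),
        zvalues=pd.Series(z, index=idx), pvalues=pd.Series(pvals, index=idx),
        sigma2_b=lam * s2e, sigma2_e=s2e, lambda_=lam,
        loglik=-0.5 * dev, n_obs=prof.n_obs, n_groups=prof.n_groups,
        boundary=boundary, converged=True, cov_params=cov,
        terms=terms or {}, _profile=prof, _y=prof.y_stats(y)["y"],
    )


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """Build the design for ``spec`` and fit the Gaussian mixed model."""
    d = build_design(data, spec)
    return fit_lmm_ml(d.y, d.X, d.groups, colnames=d.colnames, terms=d.terms)


# ---------------------------------------------------------------------------
# Semi-partial R^2
# ---------------------------------------------------------------------------

def _term_is_within(prof: _ProfileData, cols: list[int]) -> bool:
    """A term is within-participant if any of its columns varies within groups."""
    for c in cols:
        col = prof.X[:, c]
        means = np.bincount(prof.codes, weights=col) / prof.n_i
        if np.max(np.abs(col - means[prof.codes])) > 1e-10:
            return True
    return False


def _denominator_dof(prof: _ProfileData, within: bool) -> int:
    rank_x = np.linalg.matrix_rank(prof.X)
    if within:
        return prof.n_obs - rank_x - (prof.n_groups - 1)
    # between: one row per group (group means of X), rank of that design
    gm = prof.Sx / prof.n_i[:, None]
    return prof.n_groups - np.linalg.matrix_rank(gm)


def partial_r2(fit: LmmFit, term: str, n_boot: int = 0,
               rng: np.random.Generator | None = None,
               ci_level: float = 0.95) -> dict:
    """Semi-partial R^2 for one fixed-effect term, qF/(qF + nu).

    F is the Wald F for the term's coefficients; nu is the containment-rule
    denominator dof (within-participant terms: n_obs - rank(X) -
    (n_participants - 1); between terms: n_participants - rank of the
    between design). ``n_boot`` > 0 adds a parametric-bootstrap percentile
    CI (seeded via ``rng``).
    """
    if term not in fit.terms:
        raise ValidationError(f"term {term!r} not in fit (have {list(fit.terms)})")
    prof = fit._profile
    if prof is None:
        raise ValidationError("fit lacks stored design; refit with fit_lmm_ml")
    cols = fit.terms[term]
    q = len(cols)
    within = _term_is_within(prof, cols)
    nu = _denominator_dof(prof, within)
    if nu <= 0:
        raise ValidationError(f"non-positive denominator dof ({nu}) for term {term!r}")

    def _r2_from(beta: np.ndarray, cov: np.ndarray) -> float:
        bc = beta[cols]
        w = float(bc @ np.linalg.solve(cov[np.ix_(cols, cols)], bc))
        f = w / q
        return q * f / (q * f + nu)

    beta = fit.params.to_numpy()
    out = {"term": term, "r2": _r2_from(beta, fit.cov_params), "q": q,
           "nu": nu, "within": within}
    if n_boot > 0:
        rng = rng or np.random.default_rng()
        xb = prof.X @ beta
        draws = np.empty(n_boot)
        for r in range(n_boot):
            b = rng.normal(0.0, np.sqrt(fit.sigma2_b), prof.n_groups)
            ystar = xb + b[prof.codes] + rng.normal(0.0, np.sqrt(fit.sigma2_e), prof.n_obs)
            lam, bhat, s2e, A, _, _ = _fit_profiled(prof, ystar)
            draws[r] = _r2_from(bhat, s2e * np.linalg.inv(A))
        lo = (1.0 - ci_level) / 2.0
        out["ci"] = (float(np.quantile(draws, lo)), float(np.quantile(draws, 1 - lo)))
    return out


# ---------------------------------------------------------------------------
# Negative-binomial GLMM via Laplace approximation
# ---------------------------------------------------------------------------

def _nb_loglik_terms(y, mu, theta):
    """Pointwise NB2 log-pmf with mean mu and dispersion theta."""
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1.0) + theta * np.log(theta)
            + y * np.log(mu) - (theta + y) * np.log(theta + mu))


def _nb_inner_mode(eta0, y, codes, n_groups, s2b, theta,
                   b0=None, tol=1e-10, max_iter=100):
    """Vectorized damped Newton for the per-participant random-effect modes.

    The penalized log-likelihood is strictly concave in each b_i, so Newton
    with step halving is globally convergent.
    """
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    # clip the linear predictor: exp overflows poison the line search during
    # the outer optimization's exploratory steps
    _eta = lambda b: np.clip(eta0 + b[codes], -30.0, 30.0)

    def grad_hess(b):
        mu = np.exp(_eta(b))
        g_obs = y - (theta + y) * mu / (theta + mu)
        h_obs = (theta + y) * theta * mu / (theta + mu) ** 2
        g = np.bincount(codes, weights=g_obs, minlength=n_groups) - b / s2b
        h = np.bincount(codes, weights=h_obs, minlength=n_groups) + 1.0 / s2b
        return g, h

    def pen_ll(b):
        mu = np.exp(_eta(b))
        ll = np.bincount(codes, weights=_nb_loglik_terms(y, mu, theta),
                         minlength=n_groups)
        return ll - 0.5 * b ** 2 / s2b

    f = pen_ll(b)
    for _ in range(max_iter):
        g, h = grad_hess(b)
        # Newton decrement |g|/h is scale invariant in b, unlike |g| whose
        # scale blows up as s2b -> 0
        if np.max(np.abs(g) / h) < tol:
            break
        step = g / h
        # per-group step halving where the objective drops; the acceptance
        # tolerance is relative because gammaln at large theta leaves an
        # absolute noise floor well above machine epsilon
        for _ in range(40):
            b_new = b + step
            f_new = pen_ll(b_new)
            worse = f_new < f - 1e-8 * (1.0 + np.abs(f))
            if not worse.any():
                break
            step[worse] *= 0.5
        b, f = b_new, f_new
    else:
        g, h = grad_hess(b)
        if np.max(np.abs(g) / h) > 1e-5:  # stalled far from the mode
            raise ConvergenceError("inner Newton for random-effect modes diverged")
    _, h = grad_hess(b)
    return b, h


def nb_laplace_loglik(beta, sigma2_b, theta, y, X, groups, b0=None):
    """Laplace-approximate marginal log-likelihood of the NB2 GLMM."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    codes, uniq = pd.factorize(np.asarray(groups))
    n_groups = len(uniq)
    eta0 = X @ np.asarray(beta, float)
    b, h = _nb_inner_mode(eta0, y, codes, n_groups, sigma2_b, theta, b0=b0)
    mu = np.exp(np.clip(eta0 + b[codes], -30.0, 30.0))
    ll_data = float(_nb_loglik_terms(y, mu, theta).sum())
    ll_pen = float((-0.5 * b ** 2 / sigma2_b - 0.5 * np.log(2 * np.pi * sigma2_b)).sum())
    ll_lap = float((0.5 * np.log(2 * np.pi) - 0.5 * np.log(h)).sum())
    return ll_data + ll_pen + ll_lap, b


def _poisson_irls(y, X, max_iter=50):
    """Poisson GLM start values for the NB-GLMM outer optimization."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3))
    for _ in range(max_iter):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        W = mu
        z = X @ beta + (y - mu) / np.maximum(mu, 1e-10)
        XtWX = X.T @ (X * W[:, None])
        try:
            new = np.linalg.solve(XtWX, X.T @ (W * z))
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


@dataclass
class NbFit:
    """Fitted negative-binomial random-intercept GLMM (Laplace)."""

    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma2_b: float
    theta: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    terms: dict[str, list[int]] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"est": self.params, "se": self.se,
                             "z": self.zvalues, "p": self.pvalues})


def fit_nb_glmm(y, X, groups, colnames: list[str] | None = None,
                terms: dict[str, list[int]] | None = None,
                fix_sigma2_b: float | None = None,
                fix_theta: float | None = None,
                gtol: float = 1e-6) -> NbFit:
    """Fit the NB2 random-intercept GLMM with a Laplace marginal likelihood.

    Outer quasi-Newton (L-BFGS-B) over (beta, log s2_b, log theta), either
    variance parameter optionally held fixed (used for nested-model limits).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or np.any(y != np.rint(y)):
        raise ValidationError("negbin outcome must be non-negative integer counts")
    if not np.any(y > 0):
        raise DegenerateDataError("all counts are zero; no NB model identifiable")
    codes, uniq = pd.factorize(np.asarray(groups))
    p = X.shape[1]
    # optimize on unit-scaled columns: day- and year-scaled covariates
    # otherwise leave the quasi-Newton badly conditioned
    col_scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    Xs = X / col_scale

    state = {"b": None}

    def unpack(params):
        beta = params[:p]
        i = p
        if fix_sigma2_b is None:
            s2b = float(np.exp(params[i])); i += 1
        else:
            s2b = float(fix_sigma2_b)
        theta = float(np.exp(params[i])) if fix_theta is None else float(fix_theta)
        return beta, s2b, theta

    def nll(params):
        beta, s2b, theta = unpack(params)
        try:
            ll, b = nb_laplace_loglik(beta, s2b, theta, y, Xs, codes, b0=state["b"])
        except (FloatingPointError, OverflowError, ConvergenceError):
            # a pathological proposal (e.g. exploding variance) — steer the
            # line search away instead of aborting the fit
            return 1e12
        state["b"] = b
        if not np.isfinite(ll):
            return 1e12
        return -ll

    x0 = list(_poisson_irls(y, Xs))
    if fix_sigma2_b is None:
        x0.append(np.log(0.5))
    if fix_theta is None:
        x0.append(np.log(1.5))
    x0 = np.asarray(x0)
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options={"maxiter": 2000, "maxfun": 100000,
                                     "gtol": gtol, "ftol": 1e-12})
    if not res.success and np.max(np.abs(res.jac)) > 1e-2:
        raise ConvergenceError(f"NB-GLMM outer optimization failed: {res.message} "
                               f"(|grad|_inf = {np.max(np.abs(res.jac)):.3g})")
    beta_s, s2b, theta = unpack(res.x)
    beta = beta_s / col_scale

    # Wald covariance for beta from a central-difference Hessian of the
    # negative Laplace log-likelihood in the free parameters
    h = 1e-4 * np.maximum(1.0, np.abs(res.x))
    n_par = len(res.x)
    H = np.zeros((n_par, n_par))
    for i in range(n_par):
        for j in range(i, n_par):
            ei = np.zeros(n_par); ei[i] = h[i]
            ej = np.zeros(n_par); ej[j] = h[j]
            fpp = nll(res.x + ei + ej)
            fpm = nll(res.x + ei - ej)
            fmp = nll(res.x - ei + ej)
            fmm = nll(res.x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se = se_all[:p] / col_scale  # undo the internal column scaling
    names = colnames or [f"x{i}" for i in range(p)]
    idx = pd.Index(names)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return NbFit(
        params=pd.Series(beta, index=idx), se=pd.Series(se, index=idx),
        zvalues=pd.Series(z, index=idx), pvalues=pd.Series(pvals, index=idx),
        sigma2_b=s2b, theta=theta, loglik=float(-res.fun),
        n_obs=len(y), n_groups=len(uniq), converged=bool(res.success),
        terms=terms or {},
    )


def fit_nb(data: pd.DataFrame, spec: ModelSpec) -> NbFit:
    """Build the design for ``spec`` and fit the count model."""
    d = build_design(data, spec)
    return fit_nb_glmm(d.y, d.X, d.groups, colnames=d.colnames, terms=d.terms)


# ---------------------------------------------------------------------------
# Missingness diagnostics
# ---------------------------------------------------------------------------

def missingness_diagnostics(
    data: pd.DataFrame,
    continuous: tuple[str, ...] = ("age_admission", "admission_edeq", "percent_ebw"),
    categorical: tuple[str, ...] = ("diagnosis", "comorbid", "gender", "loc_admit",
                                    "discharge_reason"),
    score_columns: tuple[str, ...] = ("edeq_global", "phq9", "gad7"),
) -> pd.DataFrame:
    """Baseline comparisons of completers vs non-completers.

    A participant completes a timepoint when any score column is present on
    that row; an absent row counts as non-completion. Continuous baseline
    variables are compared by standardized mean difference
    (mean difference / pooled SD), categorical ones by a chi-square
    statistic. Completion rates per timepoint are included as ``_rate`` rows.
    """
    admission = data[data["timepoint"] == "admission"].set_index("participant_id")
    out = []
    for tp in ("stepdown", "discharge"):
        rows = data[data["timepoint"] == tp]
        completed = set(rows.loc[rows[list(score_columns)].notna().any(axis=1),
                                 "participant_id"])
        eligible = set(rows["participant_id"]) if tp == "stepdown" else set(
            admission.index)
        flags = pd.Series({pid: pid in completed for pid in eligible})
        rate = float(flags.mean()) if len(flags) else float("nan")
        out.append({"timepoint": tp, "variable": "_rate", "statistic": "completion_rate",
                    "value": rate, "n_eligible": len(flags)})
        base = admission.loc[admission.index.intersection(flags.index)]
        comp = flags.reindex(base.index)
        for var in continuous:
            if var not in base.columns:
                continue
            x1 = base.loc[comp, var].dropna()
            x0 = base.loc[~comp, var].dropna()
            if len(x1) < 2 or len(x0) < 2:
                continue
            pooled = np.sqrt((x1.var(ddof=1) + x0.var(ddof=1)) / 2.0)
            smd = (x1.mean() - x0.mean()) / pooled if pooled > 0 else 0.0
            out.append({"timepoint": tp, "variable": var, "statistic": "smd",
                        "value": float(smd), "n_eligible": len(flags)})
        for var in categorical:
            if var not in base.columns:
                continue
            tab = pd.crosstab(base[var], comp)
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                continue
            chi2 = stats.chi2_contingency(tab, correction=False)[0]
            out.append({"timepoint": tp, "variable": var, "statistic": "chi2",
                        "value": float(chi2), "n_eligible": len(flags)})
    return pd.DataFrame(out)
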