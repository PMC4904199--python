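"""Multilevel models, likelihood-ratio tests, random-structure pruning,
follow-up contrasts, and the robust two-sample check.

Model construction (factor coding, interaction columns, random-effect
design) is owned here; the numerical optimisation of the mixed model is
delegated to :class:`statsmodels` ``MixedLM``. All fits use maximum
likelihood (not REML) because every reported test is a likelihood-ratio
test on fixed effects.

Factor reference levels are fixed: low light, right hemifield, left
hemisphere, lower vertical field. Time-on-task enters as the trial
number rescaled to [0, 1] (``trial_norm``), which leaves all LRTs
invariant while conditioning the optimiser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import OLS
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

FACTOR_LEVELS: dict[str, list[str]] = {
    "light_condition": ["low", "medium", "high"],
    "hemifield": ["right", "left"],
    "hemisphere": ["left", "right"],
    "vertical_field": ["lower", "upper"],
    "direction": ["up", "down"],
    "quadrant": ["UL", "UR", "LL", "LR"],
}


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model specification and design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A mixed model: outcome, fixed terms, and the random structure.

    ``fixed`` lists term names; a term is a data column (continuous), a
    known factor (dummy-coded against its reference level), or an
    interaction written ``a:b``. ``re_terms`` are by-group random-effect
    columns over ``groups`` ('1' for the intercept, else a term name);
    ``vc_terms`` adds iid variance components for factors nested inside
    the groups (e.g. hemisphere within participant).
    """

    outcome: str
    fixed: tuple[str, ...]
    groups: str = "participant_id"
    re_terms: tuple[str, ...] = ("1",)
    vc_terms: tuple[str, ...] = ()

    def drop_fixed(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ValueError(f"term {term!r} not in fixed part")
        return replace(self, fixed=tuple(t for t in self.fixed
                                         if t != term))

    def drop_random(self, term: str) -> "ModelSpec":
        if term not in self.re_terms:
            raise ValueError(f"term {term!r} not in random part")
        return replace(self, re_terms=tuple(t for t in self.re_terms
                                            if t != term))


def _base_columns(data: pd.DataFrame, name: str) -> pd.DataFrame:
    """Numeric columns for a single (non-interaction) term."""
    if name == "1":
        return pd.DataFrame({"Intercept": np.ones(len(data))},
                            index=data.index)
    if name in FACTOR_LEVELS and name in data.columns:
        levels = FACTOR_LEVELS[name]
        seen = set(data[name].unique())
        unknown = seen - set(levels)
        if unknown:
            raise ValueError(f"unknown levels {unknown} in factor {name}")
        cols = {}
        for lev in levels[1:]:
            if lev in seen:  # only levels present in the data
                cols[f"{name}[{lev}]"] = (data[name] == lev).astype(float)
        return pd.DataFrame(cols, index=data.index)
    if name not in data.columns:
        raise ValueError(f"term {name!r} is not a data column")
    col = pd.to_numeric(data[name])
    return pd.DataFrame({name: col.astype(float)}, index=data.index)


def design_matrix(data: pd.DataFrame, terms: tuple[str, ...],
                  intercept: bool = True) -> tuple[pd.DataFrame,
                                                   dict[str, list[str]]]:
    """Fixed-effect design matrix with a term -> columns map."""
    X = {}
    term_cols: dict[str, list[str]] = {}
    if intercept:
        X["Intercept"] = np.ones(len(data))
        term_cols["1"] = ["Intercept"]
    for term in terms:
        parts = term.split(":")
        blocks = [_base_columns(data, p) for p in parts]
        cols = blocks[0]
        for b in blocks[1:]:
            prod = {}
            for c1 in cols.columns:
                for c2 in b.columns:
                    prod[f"{c1}:{c2}"] = cols[c1] * b[c2]
            cols = pd.DataFrame(prod, index=data.index)
        for c in cols.columns:
            if c in X:
                raise ValueError(f"duplicate design column {c}")
            X[c] = cols[c].to_numpy()
        term_cols[term] = list(cols.columns)
    Xdf = pd.DataFrame(X, index=data.index)
    rank = np.linalg.matrix_rank(Xdf.to_numpy())
    if rank < Xdf.shape[1]:
        aliased = _find_aliased(Xdf)
        raise ValueError(f"rank-deficient fixed design; aliased columns: "
                         f"{aliased}")
    return Xdf, term_cols


def _find_aliased(X: pd.DataFrame) -> list[str]:
    aliased, keep = [], []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            aliased.append(c)
        else:
            keep.append(c)
    return aliased


def add_trial_norm(data: pd.DataFrame, col: str = "trial_number",
                   n_max: int | None = None) -> pd.DataFrame:
    """Append ``trial_norm``: trial number rescaled to [0, 1]."""
    out = data.copy()
    hi = n_max if n_max is not None else int(out[col].max())
    out["trial_norm"] = (out[col] - 1) / max(hi - 1, 1)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A maximum-likelihood fit of a :class:`ModelSpec`."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_fixed: pd.DataFrame
    llf: float
    n_obs: int
    n_params: int
    converged: bool
    term_cols: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "fixed": list(self.spec.fixed),
            "re_terms": list(self.spec.re_terms),
            "vc_terms": list(self.spec.vc_terms),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "logLik": float(self.llf),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
        }


def _vc_spec(data: pd.DataFrame, groups: np.ndarray,
             vc_terms: tuple[str, ...]) -> VCSpec | None:
    if not vc_terms:
        return None
    names, colnames, mats = [], [], []
    ugroups = pd.unique(groups)
    for term in vc_terms:
        names.append(term)
        term_cols, term_mats = [], []
        for g in ugroups:
            sub = data.loc[groups == g, term]
            dummies = pd.get_dummies(sub).astype(float)
            term_cols.append([f"{term}[{c}]" for c in dummies.columns])
            term_mats.append(dummies.to_numpy())
        colnames.append(term_cols)
        mats.append(term_mats)
    return VCSpec(names, colnames, mats)


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the model by maximum likelihood.

    With an empty random part the fit reduces to ordinary least squares
    (its ML log-likelihood), which doubles as the exact special case for
    testing. Non-convergence of the mixed optimiser is recorded in the
    result, never silently ignored.
    """
    if spec.outcome not in data.columns:
        raise ValueError(f"outcome {spec.outcome!r} not in data")
    y = pd.to_numeric(data[spec.outcome]).to_numpy(float)
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")
    X, term_cols = design_matrix(data, spec.fixed)

    if not spec.re_terms and not spec.vc_terms:
        res = OLS(y, X.to_numpy()).fit()
        n = len(y)
        sigma2 = res.ssr / n
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        params = pd.Series(res.params, index=X.columns)
        # ML covariance (sigma2 * (X'X)^-1)
        cov = pd.DataFrame(
            sigma2 * np.linalg.inv(X.T.to_numpy() @ X.to_numpy()),
            index=X.columns, columns=X.columns)
        return FitResult(spec=spec, params=params,
                         bse=pd.Series(np.sqrt(np.diag(cov)),
                                       index=X.columns),
                         cov_fixed=cov, llf=float(llf), n_obs=n,
                         n_params=X.shape[1] + 1, converged=True,
                         term_cols=term_cols)

    groups = data[spec.groups].to_numpy()
    exog_re = None
    re_names: list[str] = []
    if spec.re_terms:
        Zs = []
        for t in spec.re_terms:
            block = _base_columns(data, t)
            Zs.append(block)
            re_names.extend(block.columns)
        Z = pd.concat(Zs, axis=1)
        exog_re = Z.to_numpy()
    vcs = _vc_spec(data, groups, spec.vc_terms)

    model = MixedLM(y, X.to_numpy(), groups=groups, exog_re=exog_re,
                    exog_vc=vcs)
    res, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs is fastest but can stall on variance boundaries; fall
        # back to slower optimisers before declaring non-convergence
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=False, method=[method], maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if not np.isfinite(cand.llf):  # degenerate optimum
                continue
            if res is None or cand.llf > res.llf + 1e-9:
                res = cand
            if cand.converged:
                res, converged = cand, True
                break
        if res is not None:
            # cheap warm-started polish: guards against converged-but-
            # suboptimal solutions that would break LRT nesting
            try:
                polish = model.fit(reml=False, method=["bfgs"],
                                   maxiter=200,
                                   start_params=res.params_object)
                if np.isfinite(polish.llf) and polish.llf > res.llf + 1e-9:
                    res = polish
                    converged = bool(polish.converged) or converged
            except (np.linalg.LinAlgError, ValueError):
                pass
    if res is None:
        raise ConvergenceError("mixed-model optimisation failed")
    k_fixed = X.shape[1]
    params = pd.Series(res.fe_params, index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k_fixed, :k_fixed],
                       index=X.columns, columns=X.columns)
    n_re = 0 if exog_re is None else exog_re.shape[1]
    n_cov = n_re * (n_re + 1) // 2 + len(spec.vc_terms)
    # boundary fits can leave tiny negative variances on the diagonal
    diag = np.maximum(np.diag(cov), 0.0)
    return FitResult(spec=spec, params=params,
                     bse=pd.Series(np.sqrt(diag), index=X.columns),
                     cov_fixed=cov, llf=float(res.llf), n_obs=len(y),
                     n_params=k_fixed + n_cov + 1, converged=converged,
                     term_cols=term_cols)


# ---------------------------------------------------------------------------
# likelihood-ratio testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRTResult:
    term: str
    chi_square: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"term": self.term, "chi_square": float(self.chi_square),
                "df": int(self.df), "p_value": float(self.p_value)}


def lr_test(full: FitResult, reduced: FitResult,
            term: str = "") -> LRTResult:
    """Likelihood-ratio test of nested ML fits: chi2 = 2 dlogLik."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits use different numbers of observations")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full")
    chi = 2.0 * (full.llf - reduced.llf)
    if chi < -1e-6 * max(1.0, abs(full.llf)):
        raise ValueError("reduced model fits better; models not nested "
                         "or optimisation failed")
    chi = max(chi, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi, df))
    return LRTResult(term=term, chi_square=chi, df=df, p_value=p)


def lrt_fixed_term(spec: ModelSpec, data: pd.DataFrame, term: str
                   ) -> tuple[LRTResult, FitResult, FitResult]:
    """LRT for one fixed term: full spec vs the spec without it."""
    full = fit_mixed(spec, data)
    reduced = fit_mixed(spec.drop_fixed(term), data)
    return lr_test(full, reduced, term=term), full, reduced


# ---------------------------------------------------------------------------
# random-structure pruning
# ---------------------------------------------------------------------------

def prune_random_structure(spec: ModelSpec, data: pd.DataFrame,
                           candidates: tuple[str, ...] | None = None,
                           alpha: float = 0.05
                           ) -> tuple[ModelSpec, list[dict]]:
    """Parsimonious random-slope structure by iterative LRTs.

    The maximal model (all candidate by-group slopes) is attempted
    first and its convergence recorded. Each candidate slope, in listed
    order, is then tested by comparing the model with the slope against
    the model without it; the slope is retained only when that LRT is
    significant at ``alpha`` and the larger model converged. The random
    intercept is always kept. The audit trail records every comparison.
    """
    if candidates is None:
        candidates = tuple(t for t in spec.re_terms if t != "1")
    audit: list[dict] = []
    maximal = replace(spec, re_terms=("1",) + tuple(candidates))
    try:
        max_fit = fit_mixed(maximal, data)
        audit.append({"step": "maximal", "re_terms": list(maximal.re_terms),
                      "converged": max_fit.converged,
                      "logLik": max_fit.llf})
    except ConvergenceError:
        audit.append({"step": "maximal", "re_terms": list(maximal.re_terms),
                      "converged": False, "logLik": None})
    if not candidates:
        return maximal, audit

    kept: list[str] = []
    for term in candidates:
        base = replace(spec, re_terms=("1",) + tuple(kept))
        trial = replace(spec, re_terms=("1",) + tuple(kept + [term]))
        entry = {"step": "candidate", "term": term,
                 "converged": False, "chi_square": None, "p_value": None,
                 "retained": False}
        try:
            fit_base = fit_mixed(base, data)
            fit_trial = fit_mixed(trial, data)
            entry["converged"] = fit_trial.converged
            if fit_trial.converged and fit_trial.llf >= fit_base.llf - 1e-8:
                lrt = lr_test(fit_trial, fit_base, term=term)
                entry["chi_square"] = lrt.chi_square
                entry["p_value"] = lrt.p_value
                if lrt.p_value < alpha:
                    kept.append(term)
                    entry["retained"] = True
        except ConvergenceError:
            pass
        audit.append(entry)
    final = replace(spec, re_terms=("1",) + tuple(kept))
    # ensure the final structure itself fits
    final_fit = fit_mixed(final, data)
    if not final_fit.converged and kept:
        raise ConvergenceError("pruned structure failed to converge")
    audit.append({"step": "final", "re_terms": list(final.re_terms),
                  "converged": final_fit.converged,
                  "logLik": final_fit.llf})
    return final, audit


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    name: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    p_adjusted: float
    adjustment: str

    def to_dict(self) -> dict:
        return {"name": self.name, "estimate": float(self.estimate),
                "se": float(self.se), "statistic": float(self.statistic),
                "p_value": float(self.p_value),
                "p_adjusted": float(self.p_adjusted),
                "adjustment": self.adjustment}


def linear_contrast(fit: FitResult, weights: dict[str, float]
                    ) -> tuple[float, float]:
    """Estimate and SE of a linear combination of fixed coefficients."""
    L = np.zeros(len(fit.params))
    cols = list(fit.params.index)
    for name, w in weights.items():
        if name not in cols:
            raise ValueError(f"unknown coefficient {name!r}")
        L[cols.index(name)] = w
    est = float(L @ fit.params.to_numpy())
    se = float(np.sqrt(L @ fit.cov_fixed.to_numpy() @ L))
    return est, se


def _max_t_adjust(stats_z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Single-step max-|t| adjustment under a multivariate-normal
    reference with correlation R (the default of the usual multiple-
    comparison machinery for general linear hypotheses)."""
    k = len(stats_z)
    adj = np.empty(k)
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=R,
                                    allow_singular=True, seed=0)
    for i, z in enumerate(np.abs(stats_z)):
        inside = mvn.cdf(np.full(k, z), lower_limit=np.full(k, -z))
        adj[i] = min(1.0, max(0.0, 1.0 - inside))
        # never report below the raw p of the same statistic
        raw = 2 * stats.norm.sf(z)
        adj[i] = max(adj[i], raw)
    return adj


def pairwise_contrasts(fit: FitResult, factor: str = "light_condition",
                       adjustment: str = "max-t",
                       extra_cols: dict[str, dict[str, float]] | None = None,
                       ) -> list[ContrastResult]:
    """All pairwise level contrasts of ``factor`` from a fitted model.

    Estimates and SEs come from the fitted fixed-effect covariance; with
    treatment coding the contrasts are evaluated at the reference levels
    of any interacting factors unless ``extra_cols`` supplies additional
    coefficient weights per level (e.g. interaction columns that move
    the contrast to a non-reference cell). p-values use the normal
    reference; the family is adjusted by single-step max-|t| (default),
    'holm', 'bonferroni' or 'none'.
    """
    levels = FACTOR_LEVELS.get(factor)
    if levels is None:
        raise ValueError(f"unknown factor {factor!r}")
    present = [lev for lev in levels
               if lev == levels[0] or f"{factor}[{lev}]" in fit.params.index]
    if len(present) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels "
                         "in the fit")

    def level_weights(lev: str) -> dict[str, float]:
        w: dict[str, float] = {}
        if lev != levels[0]:
            w[f"{factor}[{lev}]"] = 1.0
        if extra_cols and lev in extra_cols:
            for c, v in extra_cols[lev].items():
                w[c] = w.get(c, 0.0) + v
        return w

    names, ests, ses, Ls = [], [], [], []
    cols = list(fit.params.index)
    for i in range(1, len(present)):
        for j in range(i):
            hi, lo = present[i], present[j]
            w = level_weights(hi)
            for c, v in level_weights(lo).items():
                w[c] = w.get(c, 0.0) - v
            est, se = linear_contrast(fit, w)
            L = np.zeros(len(cols))
            for c, v in w.items():
                L[cols.index(c)] = v
            names.append(f"{hi} - {lo}")
            ests.append(est)
            ses.append(se)
            Ls.append(L)
    Lmat = np.vstack(Ls)
    cov = Lmat @ fit.cov_fixed.to_numpy() @ Lmat.T
    sd = np.sqrt(np.diag(cov))
    R = cov / np.outer(sd, sd)
    z = np.asarray(ests) / np.asarray(ses)
    p_raw = 2 * stats.norm.sf(np.abs(z))
    if adjustment == "max-t":
        p_adj = _max_t_adjust(z, R)
    elif adjustment == "bonferroni":
        p_adj = np.minimum(1.0, p_raw * len(p_raw))
    elif adjustment == "holm":
        order = np.argsort(p_raw)
        p_adj = np.empty_like(p_raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, p_raw[idx] * (len(p_raw) - rank))
            p_adj[idx] = min(1.0, running)
    elif adjustment == "none":
        p_adj = p_raw.copy()
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return [ContrastResult(name=n, estimate=e, se=s, statistic=zz,
                           p_value=pr, p_adjusted=pa,
                           adjustment=adjustment)
            for n, e, s, zz, pr, pa in zip(names, ests, ses, z, p_raw,
                                           p_adj)]


# ---------------------------------------------------------------------------
# robust two-sample comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustTestResult:
    trimmed_diff: float
    statistic: float
    p_value: float
    trim: float
    n_boot: int

    def to_dict(self) -> dict:
        return {"trimmed_diff": float(self.trimmed_diff),
                "statistic": float(self.statistic),
                "p_value": float(self.p_value),
                "trim": float(self.trim), "n_boot": int(self.n_boot)}


def _yuen_stat(x: np.ndarray, y: np.ndarray, trim: float
               ) -> tuple[float, float]:
    """Yuen-Welch statistic on trimmed means with winsorized variances.

    Applied along the last axis so the bootstrap can be vectorised.
    """
    def parts(a):
        n = a.shape[-1]
        g = int(np.floor(trim * n))
        s = np.sort(a, axis=-1)
        tmean = s[..., g:n - g].mean(axis=-1)
        wins = np.concatenate([
            np.repeat(s[..., g:g + 1], g, axis=-1),
            s[..., g:n - g],
            np.repeat(s[..., n - g - 1:n - g], g, axis=-1)], axis=-1)
        swv = wins.var(axis=-1, ddof=1)
        h = n - 2 * g
        d = (n - 1) * swv / (h * (h - 1))
        return tmean, d
    mx, dx = parts(x)
    my, dy = parts(y)
    diff = mx - my
    denom = np.sqrt(dx + dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    return diff, t


def yuen_welch_boot(x, y, trim: float = 0.20, n_boot: int = 2000,
                    seed: int = 0) -> RobustTestResult:
    """Bootstrapped Yuen-Welch test (20% trimmed means, winsorized
    variances); p from a percentile bootstrap of the statistic after
    centring each sample at its own trimmed mean."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs at least 5 observations")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    diff, t_obs = _yuen_stat(x, y, trim)
    rng = np.random.default_rng(seed)

    def trimmed_mean(a):
        n = a.size
        g = int(np.floor(trim * n))
        return np.sort(a)[g:n - g].mean()

    xc = x - trimmed_mean(x)
    yc = y - trimmed_mean(y)
    bx = rng.choice(xc, size=(n_boot, x.size), replace=True)
    by = rng.choice(yc, size=(n_boot, y.size), replace=True)
    _, t_boot = _yuen_stat(bx, by, trim)
    p = float((np.abs(t_boot) >= abs(t_obs)).mean())
    return RobustTestResult(trimmed_diff=float(diff),
                            statistic=float(t_obs), p_value=p,
                            trim=trim, n_boot=n_boot)
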