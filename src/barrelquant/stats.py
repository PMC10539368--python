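"""Inferential machinery for clustered morphology and group comparisons.

The central objects are two single-random-intercept mixed models fitted by
maximum likelihood:

* :class:`BinomialMixedModel` — a logistic regression with a per-animal
  Gaussian random intercept, for neuron-level binary outcomes (e.g. pyramidal
  vs spiny stellate morphology) clustered within animals.  The marginal
  likelihood integrates the random effect by adaptive Gauss–Hermite
  quadrature.
* :class:`LinearMixedModel` — a Gaussian random-intercept model for numeric
  per-section outcomes (e.g. double-label percentages), fitted by profiling
  the fixed effects and residual variance out of the likelihood, leaving a
  one-dimensional search over the variance ratio.

Group effects are tested with a parametric bootstrap of the likelihood-ratio
statistic (:func:`parametric_bootstrap_test`): data are re-simulated from the
fitted null model (including new random intercepts), both models are refitted
per replicate, and ``p = (1 + #{LR* >= LR_obs}) / (B + 1)``, so the smallest
attainable p-value is ``1/(B+1)``.

Utility tests: pooled log-odds ratios, Welch's t with Holm or
Benjamini–Hochberg correction, and an exact one-sample signed-rank test of a
directional location shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pooled_log_odds",
    "log_odds_ratio",
    "welch_holm",
    "directional_shift_test",
    "BinomialMixedModel",
    "LinearMixedModel",
    "MixedModelFit",
    "BootstrapTestResult",
    "parametric_bootstrap_test",
]


# ---------------------------------------------------------------------------
# pooled log-odds
# ---------------------------------------------------------------------------

def log_odds_ratio(p1: float, p0: float) -> float:
    """Log odds ratio ``ln[(p1/(1-p1)) / (p0/(1-p0))]`` between proportions."""
    for p in (p1, p0):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie strictly in (0, 1)")
    return float(np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)))


def pooled_log_odds(
    table: pd.DataFrame,
    outcome: str = "outcome",
    group: str = "group",
) -> float:
    """Pooled (cluster-ignoring) log odds ratio of a binary outcome.

    Pools observations within each of the two groups and returns the log
    odds ratio of the higher-coded group vs the reference (groups are ordered
    by sorted unique value, so 1-vs-0 or treatment-vs-control alphabetically).
    Coincides with the mixed-model fixed effect when the between-animal
    variance is zero.  Degenerate pooled proportions (0 or 1) receive a
    +0.5 continuity correction per cell, with a warning.
    """
    groups = np.sort(table[group].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    y0 = np.asarray(table.loc[table[group] == groups[0], outcome], dtype=float)
    y1 = np.asarray(table.loc[table[group] == groups[1], outcome], dtype=float)
    k0, n0 = y0.sum(), len(y0)
    k1, n1 = y1.sum(), len(y1)
    if k0 in (0, n0) or k1 in (0, n1):
        warnings.warn("degenerate pooled proportion; applying +0.5 continuity correction")
        return float(
            np.log((k1 + 0.5) / (n1 - k1 + 0.5)) - np.log((k0 + 0.5) / (n0 - k0 + 0.5))
        )
    return log_odds_ratio(k1 / n1, k0 / n0)


# ---------------------------------------------------------------------------
# Welch's t with multiplicity correction
# ---------------------------------------------------------------------------

def welch_holm(
    groups: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]],
    correction: str = "holm",
) -> pd.DataFrame:
    """Two-sided Welch's t tests for named group pairs with correction.

    Parameters
    ----------
    groups : mapping of group name to 1-d samples
    pairs : the comparisons forming the correction family
    correction : ``"holm"`` (step-down) or ``"bh"`` (Benjamini–Hochberg FDR)

    Returns a DataFrame with columns ``a, b, t, df, p_raw, p_adj``.
    Pairs where both samples have zero variance get NaN p-values, are
    flagged with a warning and excluded from the correction family.
    """
    if correction not in ("holm", "bh"):
        raise ValueError("correction must be 'holm' or 'bh'")
    rows = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("each group needs at least 2 values")
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            warnings.warn(f"zero variance in both groups for pair ({a}, {b}); p undefined")
            rows.append((a, b, np.nan, np.nan, np.nan))
            continue
        res = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append((a, b, float(res.statistic), float(res.df), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["a", "b", "t", "df", "p_raw"])
    out["p_adj"] = np.nan
    ok = out["p_raw"].notna()
    if ok.any():
        method = "holm" if correction == "holm" else "fdr_bh"
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p_raw"], method=method)[1]
    return out


# ---------------------------------------------------------------------------
# exact directional signed-rank shift test
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(d: np.ndarray, alternative: str) -> float:
    """Exact one-sided signed-rank p via the sign-flip null distribution.

    Ranks of |d| use midranks for ties; the null distribution of the
    positive-rank sum W+ is computed by dynamic programming over all 2^n
    sign assignments (ranks are doubled so midranks become integers).
    """
    n = len(d)
    r2 = np.round(2 * sps.rankdata(np.abs(d))).astype(int)  # doubled midranks
    w_obs2 = int(r2[d > 0].sum())
    total = int(r2.sum())
    # counts[w] = number of sign assignments with doubled W+ == w
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    cdf = np.cumsum(counts)
    denom = 2.0 ** n
    if alternative == "less":
        return float(cdf[w_obs2] / denom)
    return float((denom - (cdf[w_obs2 - 1] if w_obs2 > 0 else 0.0)) / denom)


def directional_shift_test(
    values: Sequence[float],
    direction: str,
    shift: float = 0.1,
    exact_max_n: int = 25,
) -> float:
    """One-sided signed-rank test of a location shift beyond ±`shift`.

    For ``direction="down"`` tests H1: the population location is below
    ``-shift`` (values are compared against −shift, one-sided less); for
    ``"up"`` tests H1: location above ``+shift``.  The null distribution is
    computed exactly (all 2^n sign flips, midranks for tied magnitudes) for
    n ≤ `exact_max_n`, else by normal approximation.  Zero differences are
    dropped (Wilcoxon convention) with a warning; an all-zero sample returns
    p = 1.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    mu0 = -shift if direction == "down" else shift
    d = values - mu0
    if np.any(d == 0):
        warnings.warn("values equal to the shifted null point dropped (ties at zero)")
        d = d[d != 0]
    if len(d) == 0:
        return 1.0
    alternative = "less" if direction == "down" else "greater"
    if len(d) <= exact_max_n:
        return _signed_rank_exact_p(d, alternative)
    res = sps.wilcoxon(d, alternative=alternative, method="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """ML fit of a single-random-intercept mixed model.

    Attributes
    ----------
    params : ndarray
        ``[b0, beta, log_sigma]`` for the binomial model (beta absent for a
        null model); linear model appends ``log_tau``.
    beta, se_beta : float
        Group fixed effect (log-odds or mean difference) and its
        observed-information standard error (NaN for null models).
    sigma_u : float
        Random-intercept standard deviation.
    llf : float
        Maximised marginal log-likelihood.
    """

    model: "object"
    params: np.ndarray
    beta: float
    se_beta: float
    sigma_u: float
    llf: float
    converged: bool
    sigma_resid: float | None = None
    boundary_sigma: bool = False
    bootstrap_p: float | None = None
    bootstrap_B: int | None = None

    def summary(self) -> str:
        kind = type(self.model).__name__
        lines = [
            f"{kind} (ML, single random intercept)",
            f"  groups (animals): {self.model.n_groups}   observations: {self.model.nobs}",
            f"  fixed effect beta : {self.beta: .4f}  (s.e. {self.se_beta:.4f})",
            f"  sigma_animal      : {self.sigma_u: .4f}"
            + ("  [boundary]" if self.boundary_sigma else ""),
        ]
        if self.sigma_resid is not None:
            lines.append(f"  sigma_residual    : {self.sigma_resid: .4f}")
        lines.append(f"  log-likelihood    : {self.llf: .4f}")
        if self.bootstrap_p is not None:
            lines.append(
                f"  parametric bootstrap p = {self.bootstrap_p:.4g} (B = {self.bootstrap_B})"
            )
        return "\n".join(lines)


_LOG_SIGMA_FLOOR = np.log(1e-6)


class BinomialMixedModel:
    """Bernoulli GLMM with logit link and a per-animal random intercept.

    ``y_ij ~ Bernoulli(logit^-1(b0 + beta*group_i + u_i))``,
    ``u_i ~ N(0, sigma^2)``.  The marginal likelihood is integrated by
    adaptive Gauss–Hermite quadrature (default 25 nodes), re-centred at the
    per-animal posterior mode with its Laplace curvature.

    Parameters
    ----------
    endog : binary outcomes, one row per neuron
    groups : animal identifiers (cluster labels)
    exog_group : 0/1 group indicator per row, or None for an intercept-only
        (null) model
    """

    def __init__(self, endog, groups, exog_group=None, n_quad: int = 25):
        self.endog = np.asarray(endog, dtype=float).ravel()
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        codes, uniques = pd.factorize(np.asarray(groups).ravel())
        self.group_idx = codes
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.nobs = len(self.endog)
        if exog_group is not None:
            self.exog_group = np.asarray(exog_group, dtype=float).ravel()
            if len(self.exog_group) != self.nobs:
                raise ValueError("exog_group length mismatch")
            self.k_fixed = 2
        else:
            self.exog_group = None
            self.k_fixed = 1
        self.n_quad = int(n_quad)
        z, w = hermgauss(self.n_quad)
        self._gh_z = z
        self._gh_logw = np.log(w) + z**2  # for exp-scaled quadrature
        # sorted-order bookkeeping so per-animal sums vectorise via reduceat
        self._order = np.argsort(self.group_idx, kind="stable")
        sorted_gi = self.group_idx[self._order]
        self._starts = np.searchsorted(sorted_gi, np.arange(self.n_groups))
        self._u_cache = None

    # -- likelihood ---------------------------------------------------------

    def _linpred(self, fixed: np.ndarray) -> np.ndarray:
        eta = np.full(self.nobs, fixed[0])
        if self.exog_group is not None:
            eta = eta + fixed[1] * self.exog_group
        return eta

    def _group_modes(self, eta: np.ndarray, sigma: float):
        """Posterior mode and curvature of the random intercept per animal.

        Newton iterations warm-start from the modes of the previous call
        (successive optimiser evaluations are nearby), which typically
        converges in 2–3 steps.
        """
        u = self._u_cache.copy() if self._u_cache is not None else np.zeros(self.n_groups)
        resid_target = np.bincount(self.group_idx, weights=self.endog, minlength=self.n_groups)
        for _ in range(40):
            p = special.expit(eta + u[self.group_idx])
            grad = resid_target - np.bincount(
                self.group_idx, weights=p, minlength=self.n_groups
            ) - u / sigma**2
            hess = -np.bincount(
                self.group_idx, weights=p * (1 - p), minlength=self.n_groups
            ) - 1.0 / sigma**2
            step = grad / hess
            u = u - step
            if np.max(np.abs(step)) < 1e-9:
                break
        self._u_cache = u
        p = special.expit(eta + u[self.group_idx])
        curv = np.bincount(self.group_idx, weights=p * (1 - p), minlength=self.n_groups) + 1.0 / sigma**2
        return u, curv

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at ``[fixed..., log_sigma]`` (AGQ)."""
        params = np.asarray(params, dtype=float)
        fixed, log_sigma = params[:-1], params[-1]
        sigma = np.exp(max(log_sigma, _LOG_SIGMA_FLOOR))
        eta = self._linpred(fixed)
        u_hat, curv = self._group_modes(eta, sigma)
        scale = np.sqrt(2.0 / curv)  # (n_groups,)
        # nodes: (n_groups, n_quad)
        u_nodes = u_hat[:, None] + scale[:, None] * self._gh_z[None, :]
        # conditional Bernoulli log-lik summed within animal, per node
        order = self._order
        eta_k = eta[order, None] + u_nodes[self.group_idx[order], :]
        ll_obs = self.endog[order, None] * eta_k - np.logaddexp(0.0, eta_k)
        ll_nodes = np.add.reduceat(ll_obs, self._starts, axis=0)
        ll_nodes += -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (u_nodes / sigma) ** 2
        ll_nodes += self._gh_logw[None, :] + np.log(scale)[:, None]
        return float(special.logsumexp(ll_nodes, axis=1).sum())

    # -- fitting ------------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        p_bar = np.clip(self.endog.mean(), 1e-3, 1 - 1e-3)
        b0 = special.logit(p_bar)
        if self.exog_group is None:
            return np.array([b0, np.log(0.3)])
        t = self.exog_group == 1
        p1 = np.clip(self.endog[t].mean(), 1e-3, 1 - 1e-3)
        p0 = np.clip(self.endog[~t].mean(), 1e-3, 1 - 1e-3)
        return np.array(
            [special.logit(p0), special.logit(p1) - special.logit(p0), np.log(0.3)]
        )

    def fit(self, start_params=None, xatol=1e-6, fatol=1e-9,
            polish=True, compute_se=True) -> MixedModelFit:
        x0 = np.asarray(start_params, dtype=float) if start_params is not None else self._start_params()
        nll = lambda p: -self.loglike(p)
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 4000},
        )
        if polish:
            res = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"xatol": xatol / 10, "fatol": fatol / 10, "maxiter": 2000},
            )
        if not res.success:
            warnings.warn("mixed-model optimiser did not report convergence")
        params = res.x
        sigma = float(np.exp(max(params[-1], _LOG_SIGMA_FLOOR)))
        boundary = params[-1] <= np.log(1e-4)
        beta = float(params[1]) if self.k_fixed == 2 else np.nan
        se_beta = self._se_beta(params) if (self.k_fixed == 2 and compute_se) else np.nan
        return MixedModelFit(
            model=self, params=params, beta=beta, se_beta=se_beta,
            sigma_u=sigma, llf=float(-res.fun), converged=bool(res.success),
            boundary_sigma=bool(boundary),
        )

    def _se_beta(self, params: np.ndarray) -> float:
        """Observed-information SE of the fixed effects via numerical Hessian."""
        from statsmodels.tools.numdiff import approx_hess

        try:
            H = approx_hess(params, self.loglike)
            cov = np.linalg.inv(-H)
            v = cov[1, 1]
            if v > 0:
                return float(np.sqrt(v))
        except np.linalg.LinAlgError:
            pass
        # sigma at its boundary leaves the full Hessian singular; condition
        # on log_sigma and invert the fixed-effect block only
        try:
            Hf = approx_hess(params[:-1],
                             lambda f: self.loglike(np.append(f, params[-1])))
            cov = np.linalg.inv(-Hf)
            v = cov[1, 1]
            return float(np.sqrt(v)) if v > 0 else np.nan
        except np.linalg.LinAlgError:
            return np.nan

    # -- simulation ---------------------------------------------------------

    def simulate(self, params: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw a new outcome vector from the model at ``params``."""
        params = np.asarray(params, dtype=float)
        sigma = np.exp(max(params[-1], _LOG_SIGMA_FLOOR))
        u = rng.normal(0.0, sigma, size=self.n_groups)
        eta = self._linpred(params[:-1]) + u[self.group_idx]
        return (rng.random(self.nobs) < special.expit(eta)).astype(float)

    def null_model(self) -> "BinomialMixedModel":
        """The nested intercept-only model (group effect removed)."""
        return BinomialMixedModel(
            self.endog, self.group_labels[self.group_idx], None, n_quad=self.n_quad
        )

    def with_endog(self, endog: np.ndarray) -> "BinomialMixedModel":
        m = BinomialMixedModel.__new__(BinomialMixedModel)
        m.__dict__.update(self.__dict__)
        m.endog = np.asarray(endog, dtype=float).ravel()
        m._u_cache = None
        return m

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome="outcome", group="group", animal="animal",
        n_quad: int = 25,
    ) -> "BinomialMixedModel":
        g = df[group]
        if g.dtype.kind not in "biuf":
            levels = np.sort(g.unique())
            if len(levels) != 2:
                raise ValueError("group column must have exactly 2 levels")
            g = (g == levels[1]).astype(float)
        return cls(df[outcome].to_numpy(), df[animal].to_numpy(), g.to_numpy(), n_quad=n_quad)


class LinearMixedModel:
    """Gaussian random-intercept model fitted by profiled maximum likelihood.

    ``y_ij = b0 + beta*group_i + u_i + e_ij`` with ``u_i ~ N(0, sigma^2)``
    and ``e_ij ~ N(0, tau^2)``.  For a fixed variance ratio
    ``theta = sigma^2/tau^2`` the GLS fixed effects and the residual variance
    have closed forms (Sherman–Morrison inverse of ``I + theta*J`` per
    cluster), leaving a one-dimensional profiled deviance minimised over
    ``log theta``.
    """

    def __init__(self, endog, groups, exog_group=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        codes, uniques = pd.factorize(np.asarray(groups).ravel())
        self.group_idx = codes
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.nobs = len(self.endog)
        self.group_sizes = np.bincount(codes, minlength=self.n_groups).astype(float)
        cols = [np.ones(self.nobs)]
        if exog_group is not None:
            eg = np.asarray(exog_group, dtype=float).ravel()
            cols.append(eg)
            self.exog_group = eg
        else:
            self.exog_group = None
        self.X = np.column_stack(cols)
        self.k_fixed = self.X.shape[1]

    # profiled pieces -------------------------------------------------------

    def _gls(self, theta: float, endog: np.ndarray):
        """GLS estimates and profiled -2loglik for variance ratio theta."""
        X, y, gi, ng = self.X, endog, self.group_idx, self.n_groups
        n_i = self.group_sizes
        c_i = theta / (1.0 + theta * n_i)  # Sherman–Morrison weights
        Sx = np.vstack([np.bincount(gi, weights=X[:, j], minlength=ng) for j in range(self.k_fixed)]).T
        Sy = np.bincount(gi, weights=y, minlength=ng)
        XtVX = X.T @ X - (Sx * c_i[:, None]).T @ Sx
        XtVy = X.T @ y - (Sx * c_i[:, None]).T @ Sy
        b = np.linalg.solve(XtVX, XtVy)
        r = y - X @ b
        Sr = np.bincount(gi, weights=r, minlength=ng)
        quad = r @ r - c_i @ Sr**2
        tau2 = quad / self.nobs
        logdet = np.log1p(theta * n_i).sum()
        m2ll = self.nobs * (np.log(2 * np.pi * tau2) + 1.0) + logdet
        return b, tau2, XtVX, m2ll

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at ``[fixed..., log_sigma, log_tau]``."""
        params = np.asarray(params, dtype=float)
        b = params[: self.k_fixed]
        sigma2 = np.exp(2 * params[self.k_fixed])
        tau2 = np.exp(2 * params[self.k_fixed + 1])
        theta = sigma2 / tau2
        n_i = self.group_sizes
        c_i = theta / (1.0 + theta * n_i)
        r = self.endog - self.X @ b
        Sr = np.bincount(self.group_idx, weights=r, minlength=self.n_groups)
        quad = (r @ r - c_i @ Sr**2) / tau2
        logdet = self.nobs * np.log(tau2) + np.log1p(theta * n_i).sum()
        return float(-0.5 * (self.nobs * np.log(2 * np.pi) + logdet + quad))

    def fit(self, start_params=None, **_ignored) -> MixedModelFit:
        def prof(log_theta):
            return self._gls(np.exp(log_theta), self.endog)[3]

        res = optimize.minimize_scalar(prof, bounds=(-14.0, 14.0), method="bounded",
                                       options={"xatol": 1e-8})
        cand = [(prof(res.x), res.x)]
        cand.append((self._gls(0.0, self.endog)[3], -np.inf))  # sigma = 0 boundary
        m2ll, log_theta = min(cand, key=lambda t: t[0])
        theta = np.exp(log_theta) if np.isfinite(log_theta) else 0.0
        b, tau2, XtVX, _ = self._gls(theta, self.endog)
        sigma2 = theta * tau2
        boundary = theta < 1e-10
        beta = float(b[1]) if self.k_fixed == 2 else np.nan
        if self.k_fixed == 2:
            cov = np.linalg.inv(XtVX) * tau2
            se_beta = float(np.sqrt(cov[1, 1]))
        else:
            se_beta = np.nan
        params = np.concatenate([
            b, [0.5 * np.log(max(sigma2, 1e-300)), 0.5 * np.log(tau2)]
        ])
        return MixedModelFit(
            model=self, params=params, beta=beta, se_beta=se_beta,
            sigma_u=float(np.sqrt(sigma2)), llf=-0.5 * m2ll, converged=True,
            sigma_resid=float(np.sqrt(tau2)), boundary_sigma=bool(boundary),
        )

    def simulate(self, params: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        b = params[: self.k_fixed]
        sigma = np.exp(params[self.k_fixed])
        tau = np.exp(params[self.k_fixed + 1])
        u = rng.normal(0.0, sigma, size=self.n_groups)
        return self.X @ b + u[self.group_idx] + rng.normal(0.0, tau, size=self.nobs)

    def null_model(self) -> "LinearMixedModel":
        return LinearMixedModel(self.endog, self.group_labels[self.group_idx], None)

    def with_endog(self, endog: np.ndarray) -> "LinearMixedModel":
        m = LinearMixedModel.__new__(LinearMixedModel)
        m.__dict__.update(self.__dict__)
        m.endog = np.asarray(endog, dtype=float).ravel()
        return m

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome="outcome", group="group", animal="animal"
    ) -> "LinearMixedModel":
        g = df[group]
        if g.dtype.kind not in "biuf":
            levels = np.sort(g.unique())
            if len(levels) != 2:
                raise ValueError("group column must have exactly 2 levels")
            g = (g == levels[1]).astype(float)
        return cls(df[outcome].to_numpy(), df[animal].to_numpy(), g.to_numpy())


# ---------------------------------------------------------------------------
# parametric bootstrap likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class BootstrapTestResult:
    """Parametric-bootstrap LRT of the group effect."""

    p_value: float
    stat_obs: float
    B: int
    n_exceed: int
    n_failed: int
    stats: np.ndarray = field(repr=False)


def parametric_bootstrap_test(
    alt_fit: MixedModelFit,
    B: int = 4999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapTestResult:
    """Test the group fixed effect by simulating from the fitted null model.

    The likelihood-ratio statistic ``2*(ll_alt - ll_null)`` is recomputed on
    ``B`` datasets simulated from the ML fit of the *null* model (new random
    intercepts per replicate); ``p = (1 + #{LR* >= LR_obs}) / (B + 1)``, so
    p is never 0 and its granularity is ``1/(B+1)``.  Replicates whose refit
    fails are dropped (warning if more than 5% drop).
    """
    model = alt_fit.model
    if model.exog_group is None:
        raise ValueError("alternative fit must include a group effect")
    if rng is None:
        rng = np.random.default_rng(seed)
    null = model.null_model()
    null_fit = null.fit()
    stat_obs = 2.0 * (alt_fit.llf - null_fit.llf)
    # warm starts: replicates are drawn at the null fit, so its parameters
    # (with a zero group effect spliced in for the alternative) are close
    start_null = null_fit.params
    if isinstance(model, BinomialMixedModel):
        start_alt = np.insert(start_null, 1, 0.0)
        fast = {"xatol": 1e-4, "fatol": 1e-6, "polish": False, "compute_se": False}
    else:
        start_alt, fast = None, {}
    stats_b, n_failed = [], 0
    for _ in range(B):
        y_star = null.simulate(null_fit.params, rng)
        try:
            f_alt = model.with_endog(y_star).fit(start_params=start_alt, **fast)
            f_null = null.with_endog(y_star).fit(start_params=start_null, **fast)
            stats_b.append(max(0.0, 2.0 * (f_alt.llf - f_null.llf)))
        except Exception:
            n_failed += 1
    stats_b = np.asarray(stats_b)
    if n_failed > 0.05 * B:
        warnings.warn(f"{n_failed} of {B} bootstrap replicates failed to refit")
    b_eff = len(stats_b)
    n_exceed = int((stats_b >= stat_obs - 1e-10).sum())
    p = (1.0 + n_exceed) / (b_eff + 1.0)
    alt_fit.bootstrap_p = p
    alt_fit.bootstrap_B = b_eff
    return BootstrapTestResult(
        p_value=p, stat_obs=float(stat_obs), B=b_eff,
        n_exceed=n_exceed, n_failed=n_failed, stats=stats_b,
    )
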