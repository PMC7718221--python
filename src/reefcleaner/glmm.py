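"""Random-intercept GLMM fitting and inference.

Two families are supported, matching the analysis models used throughout
the pipeline:

* ``binomial-probit`` — event counts out of opportunity trials, probit
  link, prior weights = trials (responses are proportions).
* ``gaussian-log`` — strictly positive transformed duration responses,
  Gaussian errors, log link, optional variance weights.

Fitting follows the penalized iteratively reweighted least squares (PIRLS)
scheme with independent random intercepts ``b_g = sigma * theta_g * u_g``,
``u ~ N(0, I)``.  The default ``agq0`` mode profiles the variance
parameters on the penalized working problem, jointly updating fixed
effects and random-intercept modes (the fast no-quadrature mode of common
mixed-model software); ``laplace`` mode additionally maximizes the
Laplace-approximated marginal likelihood over fixed effects and variance
parameters.  Log-likelihoods are comparable across nested fits run in the
same mode, which is what the likelihood-ratio machinery relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve

from .design import DesignInfo, build_design
from .errors import (
    InvalidArgumentError,
    InvalidComparisonError,
    NonEstimableError,
    NotApplicableError,
    SchemaError,
)

BINOMIAL_PROBIT = "binomial-probit"
GAUSSIAN_LOG = "gaussian-log"

MAX_PIRLS_ITER = 200
PIRLS_TOL = 1e-8
_SINGULAR_THETA = 1e-4


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``response`` names the response column: event counts for the binomial
    family (with ``trials`` naming the denominator column) or the positive
    transformed-duration value for the Gaussian family.  ``fixed_terms``
    are data columns (categorical columns expand to treatment contrasts;
    the nested syntax ``"x:g"`` gives per-level slopes).  ``random_terms``
    name grouping columns receiving independent random intercepts.
    """

    response: str
    family: str
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ()
    trials: str | None = None
    weights: str | None = None

    def __post_init__(self):
        if self.family not in (BINOMIAL_PROBIT, GAUSSIAN_LOG):
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.family == BINOMIAL_PROBIT and self.trials is None:
            raise InvalidArgumentError("binomial-probit models need a trials column")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_terms", tuple(self.random_terms))

    def drop_term(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise InvalidArgumentError(f"term {term!r} not in model")
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))

    def add_term(self, term: str) -> "ModelSpec":
        return replace(self, fixed_terms=self.fixed_terms + (term,))

    def with_terms(self, terms) -> "ModelSpec":
        return replace(self, fixed_terms=tuple(terms))

    def without_random(self, term: str) -> "ModelSpec":
        return replace(self, random_terms=tuple(t for t in self.random_terms if t != term))


@dataclass
class FitResult:
    """Fitted coefficients plus the diagnostics downstream stages consume."""

    spec: ModelSpec
    mode: str
    converged: bool
    singular: bool
    coefficients: pd.Series
    se: pd.Series
    z: pd.Series
    loglik: float
    deviance: float
    n_obs: int
    n_fixed_params: int  # fixed-effect columns excluding the intercept
    re_variance: dict[str, float]
    scale: float  # residual variance (1.0 for binomial)
    theta: np.ndarray
    design_info: DesignInfo
    fitted: np.ndarray
    eta: np.ndarray
    random_effects: dict[str, pd.Series]
    cov_beta: np.ndarray
    pearson_chi2: float
    row_index: np.ndarray = field(default=None, repr=False)

    @property
    def wald_p(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.z)), index=self.z.index)

    def term_beta(self, term: str) -> float:
        """Largest-|coefficient| entry of a term (the term's standardized beta
        for single-column continuous terms)."""
        cols = self.design_info.columns_for(term)
        if not cols:
            return np.nan
        vals = [self.coefficients.iloc[c] for c in cols]
        return vals[int(np.argmax(np.abs(vals)))]


# ---------------------------------------------------------------------------
# families

_CLIP = 1e-10


class _Binomial:
    name = BINOMIAL_PROBIT

    @staticmethod
    def linkinv(eta):
        return np.clip(special.ndtr(eta), _CLIP, 1 - _CLIP)

    @staticmethod
    def mu_eta(eta):
        return np.maximum(stats.norm._pdf(eta), _CLIP)

    @staticmethod
    def variance(mu):
        return mu * (1 - mu)

    @staticmethod
    def deviance(y, mu, pw):
        return 2 * pw * (special.xlogy(y, y / mu) + special.xlogy(1 - y, (1 - y) / (1 - mu)))

    @staticmethod
    def init_eta(y, pw):
        mu0 = (y * pw + 0.5) / (pw + 1.0)
        return special.ndtri(mu0)

    @staticmethod
    def loglik_saturated(y, pw):
        k = y * pw
        const = special.gammaln(pw + 1) - special.gammaln(k + 1) - special.gammaln(pw - k + 1)
        return float(np.sum(const + special.xlogy(k, y) + special.xlogy(pw - k, 1 - y)))


class _GaussianLog:
    name = GAUSSIAN_LOG

    @staticmethod
    def linkinv(eta):
        return np.exp(np.clip(eta, -700, 700))

    mu_eta = linkinv

    @staticmethod
    def variance(mu):
        return np.ones_like(mu)

    @staticmethod
    def deviance(y, mu, pw):
        return pw * (y - mu) ** 2

    @staticmethod
    def init_eta(y, pw):
        return np.log(np.maximum(y, 1e-8))


def _family(name: str):
    return _Binomial if name == BINOMIAL_PROBIT else _GaussianLog


# ---------------------------------------------------------------------------
# numerical core


def _ridge(A: np.ndarray) -> float:
    """Tiny scale-aware diagonal boost keeping near-collinear designs
    factorizable (relative size ~1e-8, invisible in well-posed problems)."""
    d = float(np.mean(np.diag(A))) if A.size else 1.0
    return 1e-8 * max(d, 1.0)


class GlmmProblem:
    """Prepared arrays for one model on one dataset.

    Holds the response, design matrix, random-effect group codes and prior
    weights as plain numpy arrays so that repeated fits (profiling over
    theta, subsample refits via :meth:`subset`) avoid pandas overhead.
    """

    def __init__(self, y, X, group_codes, group_sizes, family, prior_weights,
                 design_info, group_names, group_levels, row_index=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.group_codes = [np.asarray(c, dtype=np.intp) for c in group_codes]
        self.group_sizes = list(group_sizes)
        self.family = family
        self.pw = np.asarray(prior_weights, dtype=float)
        self.design_info = design_info
        self.group_names = list(group_names)
        self.group_levels = list(group_levels)
        self.n = len(self.y)
        self.p = self.X.shape[1]
        self.q = int(sum(self.group_sizes))
        self.row_index = (np.arange(self.n) if row_index is None
                          else np.asarray(row_index))
        self._eye_p = np.eye(self.p)
        self._nested = self._detect_nesting()

    def _detect_nesting(self):
        """For two grouping factors, detect whether one is nested in the
        other (e.g. observations within stations); the penalized solve is
        then O(q) via a diagonal Schur complement."""
        if len(self.group_codes) != 2:
            return None
        for coarse, fine in ((0, 1), (1, 0)):
            cc, cf = self.group_codes[coarse], self.group_codes[fine]
            _, first = np.unique(cf, return_index=True)
            parent = cc[first]
            if np.array_equal(cc, parent[cf]):
                return coarse, fine, parent
        return None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_spec(cls, spec: ModelSpec, data: pd.DataFrame) -> "GlmmProblem":
        if len(data) == 0:
            raise InvalidArgumentError("empty data")
        X, info = build_design(data, spec.fixed_terms)
        fam = _family(spec.family)
        if spec.family == BINOMIAL_PROBIT:
            if spec.response not in data or spec.trials not in data:
                raise SchemaError(
                    f"missing response/trials column {spec.response!r}/{spec.trials!r}"
                )
            k = np.asarray(data[spec.response], dtype=float)
            m = np.asarray(data[spec.trials], dtype=float)
            if np.any(m < 1):
                raise SchemaError("binomial trials must be >= 1 on every row")
            if np.any(k > m) or np.any(k < 0):
                raise SchemaError("binomial successes must satisfy 0 <= successes <= trials")
            y = k / m
            pw = m
        else:
            if spec.response not in data:
                raise SchemaError(f"missing response column {spec.response!r}")
            y = np.asarray(data[spec.response], dtype=float)
            if np.any(y <= 0):
                raise SchemaError("gaussian-log responses must be strictly positive")
            pw = (np.asarray(data[spec.weights], dtype=float)
                  if spec.weights else np.ones(len(y)))
            if np.any(pw <= 0):
                raise SchemaError("weights must be strictly positive")
        codes, sizes, levels = [], [], []
        for g in spec.random_terms:
            if g not in data.columns:
                raise SchemaError(f"random-effect grouping column {g!r} not found")
            c, lev = pd.factorize(data[g], sort=True)
            codes.append(c)
            sizes.append(len(lev))
            levels.append(list(lev))
        return cls(y, X, codes, sizes, fam, pw, info,
                   list(spec.random_terms), levels)

    def subset(self, rows: np.ndarray) -> "GlmmProblem":
        """Row-subset problem (re-factorizes groups to drop empty levels)."""
        codes, sizes, levels = [], [], []
        for c, lev in zip(self.group_codes, self.group_levels):
            sub = c[rows]
            uniq, new = np.unique(sub, return_inverse=True)
            codes.append(new)
            sizes.append(len(uniq))
            levels.append([lev[i] for i in uniq])
        return GlmmProblem(self.y[rows], self.X[rows], codes, sizes, self.family,
                           self.pw[rows], self.design_info, self.group_names,
                           levels, row_index=self.row_index[rows])

    def drop_columns(self, cols) -> "GlmmProblem":
        """Problem with the given design columns removed (for drop-term LRTs)."""
        keep = [j for j in range(self.p) if j not in set(cols)]
        info = DesignInfo(
            terms=tuple(t for t in self.design_info.terms
                        if set(self.design_info.term_columns[t]) - set(cols)
                        or not self.design_info.term_columns[t]),
            column_names=[self.design_info.column_names[j] for j in keep],
            term_columns={
                t: [keep.index(j) for j in js if j in keep]
                for t, js in self.design_info.term_columns.items()
                if any(j in keep for j in js)
            },
            categorical_levels=dict(self.design_info.categorical_levels),
            nested_skipped=dict(self.design_info.nested_skipped),
        )
        return GlmmProblem(self.y, self.X[:, keep], self.group_codes,
                           self.group_sizes, self.family, self.pw, info,
                           self.group_names, self.group_levels,
                           row_index=self.row_index)

    # -- penalized weighted least squares -----------------------------------

    def _pwls(self, W, z, theta, compute_cov: bool = False):
        """One penalized WLS solve; returns beta, u, logdet(M), cov_beta.

        ``cov_beta`` is only assembled when requested (it is needed once,
        at packaging time, not inside the PIRLS loop)."""
        X, p = self.X, self.p
        eye_p = self._eye_p
        Xw = X * W[:, None]
        XtWX = Xw.T @ X
        XtWz = Xw.T @ z
        if self.q == 0:
            cf = cho_factor(XtWX + _ridge(XtWX) * eye_p, check_finite=False)
            beta = cho_solve(cf, XtWz, check_finite=False)
            cov = cho_solve(cf, eye_p, check_finite=False) if compute_cov else None
            return beta, np.zeros(0), 0.0, cov
        if len(self.group_codes) == 1:
            # single grouping factor: M is diagonal, avoid the Cholesky
            ca, ta = self.group_codes[0], theta[0]
            qa = self.group_sizes[0]
            mdiag = 1.0 + ta * ta * np.bincount(ca, W, minlength=qa)
            UtWX = ta * np.column_stack(
                [np.bincount(ca, Xw[:, j], minlength=qa) for j in range(p)])
            UtWz = ta * np.bincount(ca, W * z, minlength=qa)
            logdet = float(np.sum(np.log(mdiag)))
            S = UtWX / mdiag[:, None]
            sz = UtWz / mdiag
            Xd = XtWX - UtWX.T @ S
            rb = XtWz - UtWX.T @ sz
            cfx = cho_factor(Xd + _ridge(Xd) * eye_p, check_finite=False)
            beta = cho_solve(cfx, rb, check_finite=False)
            u = sz - S @ beta
            cov = cho_solve(cfx, eye_p, check_finite=False) if compute_cov else None
            return beta, u, logdet, cov
        if self._nested is not None:
            return self._pwls_nested(W, z, theta, Xw, XtWX, XtWz, compute_cov)
        # assemble U'WU (+I), U'WX, U'Wz blockwise without forming U densely
        q = self.q
        offs = np.cumsum([0] + self.group_sizes)
        M = np.eye(q)
        UtWX = np.zeros((q, p))
        UtWz = np.zeros(q)
        for a, (ca, ta) in enumerate(zip(self.group_codes, theta)):
            qa = self.group_sizes[a]
            sl_a = slice(offs[a], offs[a + 1])
            M[sl_a, sl_a] += np.diag(ta * ta * np.bincount(ca, W, minlength=qa))
            UtWX[sl_a] = ta * np.column_stack(
                [np.bincount(ca, Xw[:, j], minlength=qa) for j in range(p)])
            UtWz[sl_a] = ta * np.bincount(ca, W * z, minlength=qa)
            for b in range(a + 1, len(self.group_codes)):
                cb, tb = self.group_codes[b], theta[b]
                qb = self.group_sizes[b]
                sl_b = slice(offs[b], offs[b + 1])
                cross = np.bincount(ca * qb + cb, W * ta * tb,
                                    minlength=qa * qb).reshape(qa, qb)
                M[sl_a, sl_b] += cross
                M[sl_b, sl_a] += cross.T
        cf = cho_factor(M, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        S = cho_solve(cf, UtWX, check_finite=False)   # M^{-1} U'WX
        sz = cho_solve(cf, UtWz, check_finite=False)
        Xd = XtWX - UtWX.T @ S
        rb = XtWz - UtWX.T @ sz
        cfx = cho_factor(Xd + _ridge(Xd) * self._eye_p, check_finite=False)
        beta = cho_solve(cfx, rb, check_finite=False)
        u = sz - S @ beta
        cov = cho_solve(cfx, self._eye_p, check_finite=False) if compute_cov else None
        return beta, u, logdet, cov

    def _pwls_nested(self, W, z, theta, Xw, XtWX, XtWz, compute_cov):
        """Penalized solve for two nested grouping factors in O(q).

        With the fine factor nested in the coarse one, the off-diagonal
        block of M couples each fine level to exactly one coarse level, so
        the Schur complement of M on the fine block is diagonal."""
        ic, i_f, parent = self._nested
        p = self.p
        ca, cf = self.group_codes[ic], self.group_codes[i_f]
        qa, qf = self.group_sizes[ic], self.group_sizes[i_f]
        tc, tf = theta[ic], theta[i_f]
        wa = np.bincount(ca, W, minlength=qa)
        wf = np.bincount(cf, W, minlength=qf)
        A = 1.0 + tc * tc * wa
        D = 1.0 + tf * tf * wf
        c = tc * tf * wf  # one nonzero per fine level, at its parent row
        S = A - np.bincount(parent, c * c / D, minlength=qa)
        logdet = float(np.sum(np.log(D)) + np.sum(np.log(S)))

        def msolve(Ra, Rf):
            # apply M^{-1} to a stacked (coarse, fine) right-hand side
            Tf = Rf / D[:, None]
            CT = np.column_stack([np.bincount(parent, c * Tf[:, j], minlength=qa)
                                  for j in range(Rf.shape[1])])
            Va = (Ra - CT) / S[:, None]
            Vf = (Rf - c[:, None] * Va[parent]) / D[:, None]
            return Va, Vf

        Ra = tc * np.column_stack([np.bincount(ca, Xw[:, j], minlength=qa)
                                   for j in range(p)])
        Rf = tf * np.column_stack([np.bincount(cf, Xw[:, j], minlength=qf)
                                   for j in range(p)])
        ra_z = tc * np.bincount(ca, W * z, minlength=qa)
        rf_z = tf * np.bincount(cf, W * z, minlength=qf)
        Va, Vf = msolve(Ra, Rf)
        va_z, vf_z = msolve(ra_z[:, None], rf_z[:, None])
        Xd = XtWX - (Ra.T @ Va + Rf.T @ Vf)
        rb = XtWz - (Ra.T @ va_z[:, 0] + Rf.T @ vf_z[:, 0])
        cfx = cho_factor(Xd + _ridge(Xd) * self._eye_p, check_finite=False)
        beta = cho_solve(cfx, rb, check_finite=False)
        ua, uf = msolve((ra_z - Ra @ beta)[:, None], (rf_z - Rf @ beta)[:, None])
        u = np.empty(self.q)
        offs = np.cumsum([0] + self.group_sizes)
        u[offs[ic]:offs[ic + 1]] = ua[:, 0]
        u[offs[i_f]:offs[i_f + 1]] = uf[:, 0]
        cov = cho_solve(cfx, self._eye_p, check_finite=False) if compute_cov else None
        return beta, u, logdet, cov

    def _eta_from(self, beta, u, theta):
        eta = self.X @ beta
        offs = np.cumsum([0] + self.group_sizes)
        for g, (c, t) in enumerate(zip(self.group_codes, theta)):
            eta = eta + t * u[offs[g]:offs[g + 1]][c]
        return eta

    def _pirls(self, theta, eta0=None, max_iter=MAX_PIRLS_ITER):
        """PIRLS at fixed theta. Returns dict with beta, u, eta, logdet,
        penalized objective pieces, convergence flag."""
        fam, y, pw = self.family, self.y, self.pw
        eta = fam.init_eta(y, pw) if eta0 is None else eta0.copy()
        beta = np.zeros(self.p)
        u = np.zeros(self.q)
        pdev_old = np.inf
        converged = False
        out = None
        for _ in range(max_iter):
            mu = fam.linkinv(eta)
            dmu = fam.mu_eta(eta)
            W = pw * dmu * dmu / fam.variance(mu)
            z = eta + (y - mu) / dmu
            beta_n, u_n, logdet, _ = self._pwls(W, z, theta)
            eta_n = self._eta_from(beta_n, u_n, theta)
            # step-halving toward the previous linear predictor if needed
            for _h in range(12):
                mu_n = fam.linkinv(eta_n)
                pdev = float(np.sum(fam.deviance(y, mu_n, pw)) + u_n @ u_n)
                if np.isfinite(pdev) and (pdev <= pdev_old or _h == 11):
                    break
                eta_n = 0.5 * (eta_n + eta)
            eta, beta, u = eta_n, beta_n, u_n
            out = dict(beta=beta, u=u, eta=eta, logdet=logdet, pdev=pdev,
                       W=W, z=z)
            if abs(pdev - pdev_old) < PIRLS_TOL * (abs(pdev) + 0.1):
                converged = True
                break
            pdev_old = pdev
        out["converged"] = converged
        return out

    def _objective(self, state):
        """Laplace / profiled deviance (-2 log marginal likelihood, up to the
        family constant) from a converged PIRLS state."""
        n = self.n
        if self.family is _Binomial:
            return state["pdev"] + state["logdet"]
        pwrss = state["pdev"]  # sum w*(y-mu)^2 + u'u
        sigma2 = pwrss / n
        return n * np.log(2 * np.pi * sigma2) + n + state["logdet"]

    # -- public fit ---------------------------------------------------------

    def fit(self, mode: str = "agq0", theta0=None):
        try:
            return self._fit(mode=mode, theta0=theta0)
        except np.linalg.LinAlgError:
            return self._failed_result(mode)

    def _failed_result(self, mode: str) -> "FitResult":
        names = self.design_info.column_names
        nanv = pd.Series(np.full(self.p, np.nan), index=names)
        return FitResult(
            spec=None, mode=mode, converged=False, singular=True,
            coefficients=nanv, se=nanv.copy(), z=nanv.copy(),
            loglik=np.nan, deviance=np.nan, n_obs=self.n,
            n_fixed_params=self.p - 1,
            re_variance={g: np.nan for g in self.group_names},
            scale=np.nan, theta=np.full(len(self.group_sizes), np.nan),
            design_info=self.design_info, fitted=np.full(self.n, np.nan),
            eta=np.full(self.n, np.nan), random_effects={},
            cov_beta=np.full((self.p, self.p), np.nan), pearson_chi2=np.nan,
            row_index=self.row_index)

    def _fit(self, mode: str = "agq0", theta0=None):
        n_groups = len(self.group_sizes)
        warm = {"eta": None}

        def profiled(theta_vec):
            theta = np.abs(np.asarray(theta_vec, dtype=float))
            st = self._pirls(theta, eta0=warm["eta"])
            if warm["eta"] is None:
                # freeze the starting predictor so the profiled objective is
                # a deterministic function of theta (simplex methods stall
                # on the hysteresis a rolling warm start introduces)
                warm["eta"] = st["eta"]
            return self._objective(st)

        if n_groups == 0:
            theta_hat = np.zeros(0)
            opt_ok = True
        elif n_groups == 1:
            hi = 25.0
            if theta0 is not None and np.size(theta0) == 1:
                hi = max(3.0 * float(np.ravel(theta0)[0]), 0.5)
            res = optimize.minimize_scalar(
                lambda t: profiled([t]), bounds=(0.0, hi), method="bounded",
                options={"xatol": 1e-4})
            if hi < 25.0 and res.x > 0.98 * hi:  # warm bracket too narrow
                res = optimize.minimize_scalar(
                    lambda t: profiled([t]), bounds=(0.0, 25.0), method="bounded",
                    options={"xatol": 1e-4})
            theta_hat = np.array([abs(res.x)])
            opt_ok = bool(res.success)
        else:
            x0 = np.ones(n_groups) if theta0 is None else np.asarray(theta0, float)
            res = optimize.minimize(
                profiled, x0, method="Nelder-Mead",
                options={"xatol": 3e-4, "fatol": 1e-4, "maxiter": 600})
            theta_hat = np.abs(res.x)
            opt_ok = bool(res.success)

        singular = bool(np.any(theta_hat < _SINGULAR_THETA)) and n_groups > 0
        theta_hat = np.where(theta_hat < _SINGULAR_THETA, 0.0, theta_hat)
        final = self._pirls(theta_hat, eta0=warm["eta"])
        converged = bool(final["converged"] and opt_ok)

        if mode == "laplace" and self.p + len(theta_hat) <= 40:
            final, theta_hat, lap_ok = self._laplace_refine(theta_hat, final)
            converged = converged and lap_ok
        return self._package(final, theta_hat, mode, converged, singular)

    def _laplace_refine(self, theta_hat, state):
        """Maximize the Laplace objective over (theta, beta) with the
        random-effect modes solved innerly."""
        p, ng = self.p, len(self.group_sizes)

        def inner_u(theta, beta, eta0):
            fam, y, pw = self.family, self.y, self.pw
            eta = eta0.copy()
            u = np.zeros(self.q)
            xb = self.X @ beta
            for _ in range(50):
                mu = fam.linkinv(eta)
                dmu = fam.mu_eta(eta)
                W = pw * dmu * dmu / fam.variance(mu)
                z = eta + (y - mu) / dmu - xb
                # solve (U'WU + I) u = U'Wz
                offs = np.cumsum([0] + self.group_sizes)
                q = self.q
                M = np.eye(q)
                rhs = np.zeros(q)
                for a, (ca, ta) in enumerate(zip(self.group_codes, theta)):
                    sl = slice(offs[a], offs[a + 1])
                    M[sl, sl] += np.diag(ta * ta * np.bincount(ca, W, self.group_sizes[a]))
                    rhs[sl] = ta * np.bincount(ca, W * z, self.group_sizes[a])
                    for b in range(a + 1, ng):
                        cb, tb = self.group_codes[b], theta[b]
                        slb = slice(offs[b], offs[b + 1])
                        cross = np.zeros((self.group_sizes[a], self.group_sizes[b]))
                        np.add.at(cross, (ca, cb), W * ta * tb)
                        M[sl, slb] += cross
                        M[slb, sl] += cross.T
                cf = cho_factor(M, lower=True)
                u_n = cho_solve(cf, rhs)
                eta_n = xb + self._eta_from(np.zeros(p), u_n, theta)
                if np.max(np.abs(eta_n - eta)) < 1e-9:
                    u, eta = u_n, eta_n
                    break
                u, eta = u_n, eta_n
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            mu = self.family.linkinv(eta)
            pdev = float(np.sum(self.family.deviance(self.y, mu, self.pw)) + u @ u)
            return dict(beta=beta, u=u, eta=eta, logdet=logdet, pdev=pdev,
                        W=None, converged=True)

        def obj(par):
            theta = np.abs(par[:ng])
            beta = par[ng:]
            return self._objective(inner_u(theta, beta, state["eta"]))

        x0 = np.concatenate([theta_hat, state["beta"]])
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-9,
                                         "maxiter": 500 * len(x0)})
        theta = np.abs(res.x[:ng])
        st = inner_u(theta, res.x[ng:], state["eta"])
        # refresh cov_beta at the solution via one PWLS linearization
        fam = self.family
        mu = fam.linkinv(st["eta"])
        dmu = fam.mu_eta(st["eta"])
        W = self.pw * dmu * dmu / fam.variance(mu)
        z = st["eta"] + (self.y - mu) / dmu
        _, _, _, covb = self._pwls(W, z, theta, compute_cov=True)
        st["cov_beta"] = covb
        return st, theta, bool(res.success)

    def _package(self, state, theta, mode, converged, singular) -> "FitResult":
        fam = self.family
        mu = fam.linkinv(state["eta"])
        if state.get("cov_beta") is None:
            dmu = fam.mu_eta(state["eta"])
            W = self.pw * dmu * dmu / fam.variance(mu)
            z = state["eta"] + (self.y - mu) / dmu
            _, _, _, covb = self._pwls(W, z, theta, compute_cov=True)
            state["cov_beta"] = covb
        names = self.design_info.column_names
        beta = pd.Series(state["beta"], index=names)
        n = self.n
        if fam is _Binomial:
            dev = float(np.sum(fam.deviance(self.y, mu, self.pw)))
            ll = (fam.loglik_saturated(self.y, self.pw)
                  - 0.5 * (dev + state["u"] @ state["u"] + state["logdet"]))
            scale = 1.0
            cov_beta = state["cov_beta"]
        else:
            rss = float(np.sum(self.pw * (self.y - mu) ** 2))
            pwrss = rss + float(state["u"] @ state["u"])
            scale = pwrss / n
            ll = (-0.5 * n * np.log(2 * np.pi * scale) - 0.5 * n
                  - 0.5 * state["logdet"] + 0.5 * float(np.sum(np.log(self.pw))))
            dev = rss
            cov_beta = state["cov_beta"] * scale
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            zval = np.where(se > 0, state["beta"] / se, np.nan)
        re_var = {g: float(scale * t * t) for g, t in zip(self.group_names, theta)}
        offs = np.cumsum([0] + self.group_sizes)
        sigma = np.sqrt(scale)
        blups = {
            g: pd.Series(sigma * t * state["u"][offs[i]:offs[i + 1]],
                         index=self.group_levels[i])
            for i, (g, t) in enumerate(zip(self.group_names, theta))
        }
        var_mu = fam.variance(mu)
        pearson = float(np.sum(self.pw * (self.y - mu) ** 2 / var_mu))
        return FitResult(
            spec=None, mode=mode, converged=converged, singular=singular,
            coefficients=beta,
            se=pd.Series(se, index=names),
            z=pd.Series(zval, index=names),
            loglik=float(ll), deviance=dev, n_obs=n,
            n_fixed_params=self.p - 1,
            re_variance=re_var, scale=float(scale), theta=theta,
            design_info=self.design_info, fitted=mu, eta=state["eta"],
            random_effects=blups, cov_beta=cov_beta, pearson_chi2=pearson,
            row_index=self.row_index,
        )


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, mode: str = "agq0") -> FitResult:
    """Fit *spec* on *data*.

    ``mode="agq0"`` is the fast profiled-working-response mode used for all
    pipeline fits; ``mode="laplace"`` additionally maximizes the
    Laplace-approximated marginal likelihood.  Non-convergence is reported
    on the returned :class:`FitResult`, never raised.
    """
    if mode not in ("agq0", "laplace"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    problem = GlmmProblem.from_spec(spec, data)
    result = problem.fit(mode=mode)
    result.spec = spec
    return result


# ---------------------------------------------------------------------------
# transforms and tests


def transform_duration(proportion, epsilon: float = 1e-4, floor: float = 1e-6):
    """Map an interaction proportion onto the positive duration-response scale.

    Returns ``|logit(p')|`` with ``p' = clip(p, epsilon, 1-epsilon)``;
    exact-zero results (p = 0.5) are floored at *floor* so the value stays
    strictly positive for log-link Gaussian modelling.
    """
    p = np.asarray(proportion, dtype=float)
    if not (0 < epsilon < 0.5):
        raise InvalidArgumentError("epsilon must be in (0, 0.5)")
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidArgumentError("proportions must lie in [0, 1]")
    pc = np.clip(p, epsilon, 1 - epsilon)
    t = np.abs(np.log(pc / (1 - pc)))
    t = np.maximum(t, floor)
    return float(t) if np.isscalar(proportion) else t


@dataclass(frozen=True)
class LRTResult:
    chi_square: float
    df: int
    p_value: float


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> LRTResult:
    """Chi-square LRT of two nested fits run in the same mode on the same data.

    Random-effect comparisons are reported at df=1 per grouping factor with
    no boundary correction (the convention mirrored throughout the
    reporting), and negative statistics from approximate likelihoods are
    clamped to zero with a warning.
    """
    if not (full.converged and reduced.converged):
        raise NonEstimableError("LRT requires two converged fits")
    if full.mode != reduced.mode or full.n_obs != reduced.n_obs:
        raise InvalidComparisonError("fits must share data and fitting mode")
    df_fixed = full.n_fixed_params - reduced.n_fixed_params
    df_random = len(full.re_variance) - len(reduced.re_variance)
    if df_fixed < 0 or df_random < 0:
        raise InvalidComparisonError("reduced model has more parameters than full")
    if full.spec is not None and reduced.spec is not None:
        if df_fixed > 0 and not set(_expanded(reduced.spec)) <= set(_expanded(full.spec)):
            raise InvalidComparisonError("reduced fixed terms are not a subset of full")
    df = df_fixed + df_random
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if df == 0:
        return LRTResult(max(chi2, 0.0), 1, 1.0) if abs(chi2) < 1e-8 else \
            LRTResult(max(chi2, 0.0), 1, float(stats.chi2.sf(max(chi2, 0.0), 1)))
    if chi2 < 0:
        if chi2 < -1e-6:
            warnings.warn(f"negative LRT statistic ({chi2:.3g}) clamped to 0")
        chi2 = 0.0
    return LRTResult(float(chi2), int(df), float(stats.chi2.sf(chi2, df)))


def _expanded(spec: ModelSpec):
    return spec.fixed_terms


def overdispersion_ratio(fit: FitResult) -> float:
    """Sum of squared Pearson residuals over residual df; >2 flags excess."""
    if fit.spec is not None and fit.spec.family != BINOMIAL_PROBIT:
        raise NotApplicableError("overdispersion ratio applies to binomial fits only")
    df = fit.n_obs - (fit.n_fixed_params + 1) - len(fit.re_variance)
    if df <= 0:
        raise InvalidArgumentError("no residual degrees of freedom")
    return float(fit.pearson_chi2 / df)


def pseudo_r2_adjusted(fit: FitResult, null_fit: FitResult) -> float:
    """Adjusted deviance-based pseudo R-squared against the intercept(+RE) model.

    ``R2 = 1 - dev(fit)/dev(null)`` adjusted as
    ``1 - (1-R2)(n-1)/(n-k-1)`` with k = fixed-effect parameters.
    """
    if fit.n_obs != null_fit.n_obs:
        raise InvalidComparisonError("fits are not on the same data")
    r2 = 1.0 - fit.deviance / null_fit.deviance
    n, k = fit.n_obs, fit.n_fixed_params
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - k - 1))


def tukey_posthoc(fit: FitResult, factor: str) -> pd.DataFrame:
    """All pairwise level contrasts of a categorical term with
    studentized-range (Tukey) adjusted p-values."""
    info = fit.design_info
    if factor not in info.categorical_levels:
        raise InvalidArgumentError(f"{factor!r} is not a categorical term of this fit")
    levels = info.categorical_levels[factor]
    if len(levels) < 3:
        raise InvalidArgumentError(
            f"{factor!r} has {len(levels)} levels; use a plain LRT for 2-level factors"
        )
    k = len(levels)
    p_total = fit.n_fixed_params + 1
    df = max(fit.n_obs - p_total, 2)
    cols = {levels[0]: None}
    for lev, j in zip(levels[1:], info.columns_for(factor)):
        cols[lev] = j
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ci = np.zeros(p_total)
            cj = np.zeros(p_total)
            if cols[levels[i]] is not None:
                ci[cols[levels[i]]] = 1.0
            if cols[levels[j]] is not None:
                cj[cols[levels[j]]] = 1.0
            c = ci - cj
            est = float(c @ fit.coefficients.to_numpy())
            se = float(np.sqrt(c @ fit.cov_beta @ c))
            q = abs(est) / se * np.sqrt(2.0) if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df))
            rows.append((levels[i], levels[j], est, se, q, p))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "estimate",
                                       "se", "q_stat", "p_adj"])
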