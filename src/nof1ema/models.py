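"""Per-individual count-regression time-series engine.

Fits log-link (quasi-)Poisson models to per-window engagement counts from a
single participant, with

* parametric EMA predictor terms reported as incidence rate ratios
  (IRR = exp(beta), the multiplicative change in expected count per unit
  predictor change),
* an optional cyclic cubic regression spline over the day of the week
  (period 7, penalized, smoothing parameter chosen by GCV), and
* ARMA(p, q)-correlated working errors estimated by iterating a penalized
  GLS step with an ARMA refit on the Pearson residuals — the single-subject
  analogue of a generalized additive mixed model, where serial correlation
  plays the role of the random-effect structure.

Structure selection compares AIC (QAIC under overdispersion) over a (p, q)
grid; univariable fits and backward elimination of predictors reuse the
selected structure. The ``amount`` outcome (seconds of engagement) is
modelled with the same machinery, treating seconds as counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.linalg import null_space, toeplitz
from scipy.special import gammaln
from statsmodels.regression.linear_model import yule_walker
from statsmodels.tsa.arima_process import arma_acf
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import pacf as sm_pacf

__all__ = [
    "ModelSpec",
    "SmoothBasis",
    "FitResult",
    "ConvergenceError",
    "build_cyclic_basis",
    "fit_count_gam",
    "estimate_dispersion",
    "acf_pacf",
    "select_structure",
    "fit_univariable",
    "backward_select",
    "irr_report",
    "percent_change",
    "percent_change_label",
]

DEFAULT_PREDICTORS = ("reminder", "motivation", "usefulness", "alcohol",
                      "lack_of_time")
DEFAULT_STRUCTURE_GRID = tuple((p, q) for p in (0, 1, 2) for q in (0, 1, 2))


class ConvergenceError(RuntimeError):
    """Raised when the penalized IRLS or the ARMA outer loop fails."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, predictors, correlation structure, smooth, family."""

    outcome: str = "frequency"
    predictors: tuple = DEFAULT_PREDICTORS
    ar_order: int = 0
    ma_order: int = 0
    seasonal_smooth: bool = True
    k: int = 5
    family: str = "auto"  # poisson | quasipoisson | auto (promote if phi large)
    dispersion_threshold: float = 1.5
    arma_method: str = "auto"  # yw (Yule-Walker, q=0 only) | mle | auto

    def __post_init__(self) -> None:
        if self.ar_order < 0 or self.ma_order < 0:
            raise ValueError("AR/MA orders must be nonnegative")
        if self.family not in ("auto", "poisson", "quasipoisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class SmoothBasis:
    """Cyclic cubic regression spline basis over [0, period).

    The spline interpolates values at k wrap-around knots; the design maps
    knot values to fitted values and the quadratic penalty is the integrated
    squared second derivative, which is exactly zero for a constant.
    """

    knots: np.ndarray
    period: float
    k: int
    _BinvD: np.ndarray
    S: np.ndarray  # k x k penalty (before identifiability constraint)
    Z: np.ndarray | None = None  # sum-to-zero constraint transform

    def design_raw(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float) % self.period
        # map points landing exactly on the last knot back into range
        h = np.diff(self.knots)
        j = np.clip(np.searchsorted(self.knots, x, side="right") - 1,
                    0, self.k - 1)
        X = np.zeros((len(x), self.k))
        for i, (xi, ji) in enumerate(zip(x, j)):
            hj = h[ji]
            d_r = self.knots[ji + 1] - xi
            d_l = xi - self.knots[ji]
            am, ap = d_r / hj, d_l / hj
            cm = (d_r**3 / hj - hj * d_r) / 6.0
            cp = (d_l**3 / hj - hj * d_l) / 6.0
            X[i, ji] += am
            X[i, (ji + 1) % self.k] += ap
            X[i] += cm * self._BinvD[ji] + cp * self._BinvD[(ji + 1) % self.k]
        return X

    def constrained(self, x) -> tuple[np.ndarray, np.ndarray]:
        """(design, penalty) in the sum-to-zero constrained parameterization."""
        X = self.design_raw(x)
        if self.Z is None:
            C = X.mean(axis=0, keepdims=True)
            self.Z = null_space(C)
        return X @ self.Z, self.Z.T @ self.S @ self.Z


def build_cyclic_basis(x, k: int = 5, period: float = 7.0) -> SmoothBasis:
    """Construct the cyclic cubic spline basis (3 <= k <= 7 knots)."""
    if not 3 <= k <= 7:
        raise ValueError("basis dimension k must satisfy 3 <= k <= 7")
    knots = np.linspace(0.0, period, k + 1)
    h = np.diff(knots)
    B = np.zeros((k, k))
    D = np.zeros((k, k))
    for j in range(k):
        jm, jp = (j - 1) % k, (j + 1) % k
        B[j, jm] += h[jm % k] / 6.0
        B[j, j] += (h[jm % k] + h[j]) / 3.0
        B[j, jp] += h[j] / 6.0
        D[j, jm] += 1.0 / h[jm % k]
        D[j, j] += -1.0 / h[jm % k] - 1.0 / h[j]
        D[j, jp] += 1.0 / h[j]
    BinvD = np.linalg.solve(B, D)
    S = D.T @ BinvD
    S = (S + S.T) / 2.0
    basis = SmoothBasis(knots=knots, period=period, k=k, _BinvD=BinvD, S=S)
    _ = np.asarray(x)  # x accepted for interface symmetry; design built lazily
    return basis


@dataclass
class FitResult:
    """A fitted (quasi-)Poisson time-series regression."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    family_used: str
    ar_params: tuple
    ma_params: tuple
    smooth_lambda: float | None
    edf: float
    loglik: float
    aic: float
    qaic: float
    working_loglik: float
    working_aic: float
    n: int
    fitted: np.ndarray
    pearson_resid: np.ndarray
    converged: bool
    fallback_used: bool
    term_names: tuple
    smooth: SmoothBasis | None = None
    smooth_coefs: np.ndarray | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)

    def wald_p(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def smooth_values(self, x) -> np.ndarray:
        """Fitted seasonal smooth (log scale, centred) at day-of-week x."""
        if self.smooth is None:
            return np.zeros(len(np.atleast_1d(x)))
        Xc, _ = self.smooth.constrained(np.atleast_1d(x))
        return Xc @ self.smooth_coefs


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _prepare(spec: ModelSpec, data: pd.DataFrame):
    df = data.reset_index(drop=True)
    n = len(df)
    if n < 20:
        raise ValueError(f"need at least 20 observations, got {n}")
    y = df[spec.outcome].to_numpy(dtype=float)
    if spec.outcome == "amount":
        y = np.rint(y)
    if np.any(y < 0) or np.any(np.isnan(y)):
        raise ValueError("outcome must be complete and nonnegative")
    if "dow" in df.columns:
        dow = df["dow"].to_numpy(dtype=float)
    elif "window_index" in df.columns:
        dow = (((df["window_index"].to_numpy(int) - 1) // 2) % 7).astype(float)
    else:
        dow = ((np.arange(n) // 2) % 7).astype(float)
    cols = []
    for name in spec.predictors:
        if name not in df.columns:
            raise ValueError(f"predictor {name!r} not in data")
        v = df[name].to_numpy(dtype=float)
        if np.any(np.isnan(v)):
            raise ValueError(f"predictor {name!r} has missing cells")
        if np.std(v) == 0:
            raise ValueError(
                f"predictor {name!r} has no within-person variance")
        cols.append(v)
    Xp = (np.column_stack(cols) if cols else np.empty((n, 0)))
    return y, Xp, dow


def _arma_correlation(phis: Sequence[float], thetas: Sequence[float],
                      n: int) -> np.ndarray:
    if not phis and not thetas:
        return np.eye(n)
    r = arma_acf(np.r_[1.0, -np.asarray(phis)], np.r_[1.0, np.asarray(thetas)],
                 lags=n)
    return toeplitz(r)


def _stationary_ar(rho: np.ndarray) -> np.ndarray:
    """Shrink Yule-Walker AR coefficients toward 0 until stationary."""
    rho = np.asarray(rho, dtype=float)
    for _ in range(40):
        roots = np.roots(np.r_[-rho[::-1], 1.0]) if rho.size else np.array([])
        if rho.size == 0 or np.all(np.abs(roots) > 1.0 + 1e-6):
            return rho
        rho = 0.9 * rho
    return np.zeros_like(rho)


def _estimate_arma(resid: np.ndarray, p: int, q: int,
                   method: str) -> tuple[tuple, tuple]:
    if p == 0 and q == 0:
        return (), ()
    use_yw = method == "yw" or (method == "auto" and q == 0)
    if use_yw and q == 0:
        rho, _ = yule_walker(resid, order=p, method="mle")
        return tuple(_stationary_ar(rho)), ()
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ARIMA(resid, order=(p, 0, q), trend="n",
                    enforce_stationarity=True,
                    enforce_invertibility=True).fit()
    return tuple(res.arparams), tuple(res.maparams)


def _pirls(y, X, P, R=None, beta0=None, max_iter=200, tol=1e-12):
    """Penalized IRLS for a log-link count model with working correlation R.

    Solves (X' A X + P) beta = X' A z with A = W^{1/2} R^{-1} W^{1/2} at each
    step. Returns beta, XtAX, F = XtAX + P, mu, and the working residual
    vector standardized by the weights.
    """
    n, pdim = X.shape
    cho = None if R is None else linalg.cho_factor(R + 1e-10 * np.eye(n))
    beta = beta0
    if beta is None:
        beta = np.zeros(pdim)
        beta[0] = math.log(y.mean() + 0.1)
    dev_old = np.inf
    for it in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        sw = np.sqrt(mu)
        Xw = X * sw[:, None]
        zw = z * sw
        if cho is None:
            XtAX = Xw.T @ Xw
            XtAz = Xw.T @ zw
        else:
            RiXw = linalg.cho_solve(cho, Xw)
            XtAX = Xw.T @ RiXw
            XtAz = RiXw.T @ zw
        F = XtAX + P
        try:
            beta_new = linalg.solve(F, XtAz, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular system in IRLS: {exc}") from exc
        dev = _deviance(y, np.exp(np.clip(X @ beta_new, -30, 30)))
        if not np.isfinite(dev):
            raise ConvergenceError("divergent deviance in IRLS")
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol or abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last step {step:.2e}, deviance {dev:.6g})")
    mu = np.exp(np.clip(X @ beta, -30, 30))
    return beta, XtAX, F, mu


def _edf(XtAX: np.ndarray, F: np.ndarray) -> float:
    return float(np.trace(linalg.solve(F, XtAX)))


_LAMBDA_GRID = np.logspace(-4, 7, 23)


def fit_count_gam(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the log-link count model described by ``spec`` to one participant.

    With ``ar_order = ma_order = 0``, no smooth and Poisson family this is an
    ordinary unpenalized Poisson GLM (and agrees with textbook IRLS to
    numerical precision). The seasonal smooth adds a GCV-penalized cyclic
    spline block; nonzero ARMA orders trigger the working-correlation outer
    loop. On ARMA estimation failure the fit falls back to independent
    errors and flags ``fallback_used``.
    """
    y, Xp, dow = _prepare(spec, data)
    n = len(y)
    names = ["intercept"] + list(spec.predictors)
    blocks = [np.ones((n, 1)), Xp]
    smooth = None
    Ssm = None
    if spec.seasonal_smooth:
        smooth = build_cyclic_basis(dow, k=spec.k)
        Xs, Ssm = smooth.constrained(dow)
        blocks.append(Xs)
        names += [f"dow_s{i}" for i in range(Xs.shape[1])]
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (collinear predictors among "
            f"{spec.predictors})")
    npar = 1 + Xp.shape[1]

    def penalty(lam: float) -> np.ndarray:
        P = np.zeros((X.shape[1], X.shape[1]))
        if Ssm is not None:
            P[npar:, npar:] = lam * Ssm
        return P

    # smoothing parameter by GCV on the independence fit
    lam = None
    if Ssm is not None:
        best = (np.inf, _LAMBDA_GRID[0], None)
        beta_ws = None
        for cand in _LAMBDA_GRID:
            try:
                beta, XtAX, F, mu = _pirls(y, X, penalty(cand), beta0=beta_ws,
                                           tol=1e-10)
            except ConvergenceError:
                continue
            beta_ws = beta
            edf = _edf(XtAX, F)
            gcv = n * _deviance(y, mu) / max(n - edf, 1e-8) ** 2
            if gcv < best[0]:
                best = (gcv, cand, beta)
        if best[2] is None:
            raise ConvergenceError("no smoothing parameter gave a stable fit")
        lam = best[1]
    P = penalty(lam) if Ssm is not None else np.zeros((X.shape[1], X.shape[1]))

    beta, XtAX, F, mu = _pirls(y, X, P)
    phis: tuple = ()
    thetas: tuple = ()
    fallback = False
    if spec.ar_order or spec.ma_order:
        try:
            for _ in range(15):
                pearson = (y - mu) / np.sqrt(mu)
                new_phis, new_thetas = _estimate_arma(
                    pearson, spec.ar_order, spec.ma_order, spec.arma_method)
                R = _arma_correlation(new_phis, new_thetas, n)
                beta, XtAX, F, mu = _pirls(y, X, P, R=R, beta0=beta)
                delta = np.max(np.abs(np.r_[new_phis, new_thetas]
                                      - np.r_[phis + (0,) * (len(new_phis) - len(phis)),
                                              thetas + (0,) * (len(new_thetas) - len(thetas))])) \
                    if (phis or thetas) else np.inf
                phis, thetas = new_phis, new_thetas
                if delta < 1e-3:
                    break
        except (ConvergenceError, linalg.LinAlgError, ValueError) as exc:
            warnings.warn(
                f"ARMA({spec.ar_order},{spec.ma_order}) correlation could not "
                f"be estimated ({exc}); falling back to independent errors")
            fallback = True
            phis, thetas = (), ()
            beta, XtAX, F, mu = _pirls(y, X, P)

    edf = _edf(XtAX, F)
    resid_df = n - edf
    if resid_df <= 0:
        raise ConvergenceError("no residual degrees of freedom")
    pearson = (y - mu) / np.sqrt(mu)
    phi = float(np.sum(pearson**2) / resid_df)
    # marginal Gaussian log-likelihood of the working model (profiled sigma^2):
    # the Poisson likelihood cannot see R, so correlation structures are
    # scored on the working-response scale, as mixed-model software does
    R_final = _arma_correlation(phis, thetas, n)
    cho_R = linalg.cho_factor(R_final + 1e-10 * np.eye(n))
    quad = float(pearson @ linalg.cho_solve(cho_R, pearson))
    sigma2 = max(quad / n, 1e-12)
    logdet_V = (2.0 * np.sum(np.log(np.diag(cho_R[0])))
                - float(np.sum(np.log(mu))))
    working_ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_V + n)
    k_work = edf + len(phis) + len(thetas) + 1
    working_aic = -2.0 * working_ll + 2.0 * k_work
    family_used = spec.family
    if spec.family == "auto":
        family_used = ("quasipoisson" if phi > spec.dispersion_threshold
                       else "poisson")
    scale = phi if family_used == "quasipoisson" else 1.0
    Finv = linalg.solve(F, np.eye(F.shape[0]), assume_a="pos")
    V = scale * (Finv @ XtAX @ Finv)
    ll = _poisson_loglik(y, mu)
    k_eff = edf + len(phis) + len(thetas)
    aic = -2.0 * ll + 2.0 * k_eff
    qaic = -2.0 * ll / max(phi, 1e-8) + 2.0 * (k_eff + 1)
    nsm = X.shape[1] - npar
    return FitResult(
        spec=spec,
        params=pd.Series(beta[:npar], index=names[:npar]),
        cov=pd.DataFrame(V[:npar, :npar], index=names[:npar],
                         columns=names[:npar]),
        dispersion=phi,
        family_used=family_used,
        ar_params=tuple(map(float, phis)),
        ma_params=tuple(map(float, thetas)),
        smooth_lambda=lam,
        edf=edf,
        loglik=ll,
        aic=aic,
        qaic=qaic,
        working_loglik=working_ll,
        working_aic=working_aic,
        n=n,
        fitted=mu,
        pearson_resid=pearson,
        converged=True,
        fallback_used=fallback,
        term_names=tuple(spec.predictors),
        smooth=smooth,
        smooth_coefs=(beta[npar:] if nsm else None),
    )


def estimate_dispersion(fit: FitResult,
                        threshold: float = 1.5) -> tuple[float, str]:
    """Pearson dispersion of a fit and the family it implies.

    phi = Pearson chi-square / residual df; the family is promoted to
    quasi-Poisson when phi exceeds ``threshold``.
    """
    if fit.n - fit.edf <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    phi = fit.dispersion
    return phi, ("quasipoisson" if phi > threshold else "poisson")


def acf_pacf(residuals: np.ndarray, max_lag: int = 10) -> dict:
    """Sample ACF/PACF with +-1.96/sqrt(n) bands and a lag-1 flag.

    A significant lag-1 autocorrelation means measurements are correlated
    with those taken 12 hours previously. Constant residuals have no
    defined autocorrelation and are reported as NaN.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < max_lag + 5:
        raise ValueError("need at least max_lag + 5 residuals")
    band = 1.96 / math.sqrt(n)
    if np.std(r) == 0:
        nan = np.full(max_lag + 1, np.nan)
        return {"acf": nan, "pacf": nan, "band": band, "lag1_significant": False,
                "defined": False}
    a = sm_acf(r, nlags=max_lag, fft=False)
    p = sm_pacf(r, nlags=max_lag, method="ywm")
    return {
        "acf": a,
        "pacf": p,
        "band": band,
        "lag1_significant": bool(abs(a[1]) > band),
        "defined": True,
    }


def select_structure(data: pd.DataFrame, spec: ModelSpec,
                     grid: Sequence[tuple] = DEFAULT_STRUCTURE_GRID
                     ) -> tuple[ModelSpec, pd.DataFrame]:
    """Choose the ARMA(p, q) error structure by information criterion.

    The full-predictor model is fitted per candidate and candidates are
    compared on the working-model AIC (marginal Gaussian likelihood of the
    standardized working residuals under the candidate's ARMA covariance,
    with profiled scale) — the count likelihood itself is invariant to the
    working correlation, so it cannot rank structures. Exact ties break
    toward smaller p + q, then smaller p.
    """
    rows = []
    fits: dict[tuple, FitResult] = {}
    for (p, q) in grid:
        cand = replace(spec, ar_order=p, ma_order=q)
        try:
            fits[(p, q)] = fit_count_gam(cand, data)
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"candidate ARMA({p},{q}) failed: {exc}")
    if not fits:
        raise ConvergenceError("every candidate correlation structure failed")
    richest = max(fits, key=lambda t: (t[0] + t[1], t[0]))
    phi_ref = fits[richest].dispersion
    quasi = (spec.family == "quasipoisson"
             or (spec.family == "auto" and phi_ref > spec.dispersion_threshold))
    for (p, q), f in fits.items():
        rows.append({"p": p, "q": q, "aic": f.aic,
                     "criterion": f.working_aic,
                     "quasi": quasi, "dispersion": f.dispersion})
    table = pd.DataFrame(rows).sort_values(["p", "q"]).reset_index(drop=True)
    best = min(rows, key=lambda r: (r["criterion"], r["p"] + r["q"], r["p"]))
    best_spec = replace(spec, ar_order=int(best["p"]), ma_order=int(best["q"]))
    return best_spec, table


def fit_univariable(data: pd.DataFrame, predictor: str,
                    structure: ModelSpec) -> FitResult:
    """Single-predictor fit carrying the selected ARMA structure and smooth."""
    return fit_count_gam(replace(structure, predictors=(predictor,)), data)


def backward_select(data: pd.DataFrame, full_spec: ModelSpec
                    ) -> tuple[FitResult, list]:
    """Stepwise elimination of redundant predictors by information criterion.

    At each step the predictor whose removal lowers the criterion (AIC, or
    QAIC under an overdispersed full model) the most is dropped; the final
    model may retain all predictors or none (an intercept + smooth model).
    Returns the final fit and the elimination trace.
    """
    current = full_spec
    fit = fit_count_gam(current, data)
    phi_ref = fit.dispersion
    quasi = (full_spec.family == "quasipoisson"
             or (full_spec.family == "auto"
                 and phi_ref > full_spec.dispersion_threshold))

    def crit(f: FitResult) -> float:
        if quasi:
            narma = len(f.ar_params) + len(f.ma_params)
            return -2.0 * f.loglik / max(phi_ref, 1e-8) + 2.0 * (f.edf + narma + 1)
        return f.aic

    trace = [{"step": 0, "removed": None, "criterion": crit(fit),
              "predictors": current.predictors}]
    step = 0
    while current.predictors:
        step += 1
        options = []
        for name in current.predictors:
            reduced = replace(current, predictors=tuple(
                pnam for pnam in current.predictors if pnam != name))
            try:
                f = fit_count_gam(reduced, data)
                options.append((crit(f), name, reduced, f))
            except (ConvergenceError, ValueError):
                continue
        if not options:
            break
        options.sort(key=lambda t: t[0])
        best_crit, name, reduced, f = options[0]
        if best_crit < crit(fit):
            current, fit = reduced, f
            trace.append({"step": step, "removed": name,
                          "criterion": best_crit,
                          "predictors": current.predictors})
        else:
            break
    return fit, trace


def percent_change(irr: float) -> float:
    """IRR expressed as percent change in the expected count."""
    return (irr - 1.0) * 100.0


def percent_change_label(irr: float) -> str:
    """Human-readable percent change: '288% increase', '48% reduction'."""
    pc = percent_change(irr)
    r = int(math.copysign(math.floor(abs(pc) + 0.5), pc))
    if r == 0:
        return "0% change"
    return f"{abs(r)}% {'increase' if r > 0 else 'reduction'}"


def irr_report(fit: FitResult, z: float = 1.96) -> pd.DataFrame:
    """IRR, 95% CI, Wald p and percent-change table for a fitted model."""
    rows = []
    p_values = fit.wald_p()
    for name in fit.term_names:
        b = float(fit.params[name])
        se = float(fit.se[name])
        irr = math.exp(b)
        rows.append({
            "predictor": name,
            "irr": irr,
            "ci_low": math.exp(b - z * se),
            "ci_high": math.exp(b + z * se),
            "p_value": float(p_values[name]),
            "percent_change": percent_change(irr),
            "label": percent_change_label(irr),
            "ar_ma": f"{fit.spec.ar_order},{fit.spec.ma_order}",
        })
    return pd.DataFrame(rows)
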