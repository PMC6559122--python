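"""Maximum-likelihood covariance-structure estimation.

Implements the classic normal-theory discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p,

with the implied covariance of the all-latent model

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta_eps,

minimized by Fisher scoring (expected-information quasi-Newton steps with
backtracking; steps that make Sigma non-positive-definite are shrunk, never
fatal).  The model chi-square is (N - 1) * F_min by default, matching the
convention under which classic LISREL output was produced; an N multiplier
is available.  Standard errors come from the inverse expected information at
the optimum (observed information optional via finite differences of the
analytic gradient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .model import MatrixModel
from .moments import SampleMoments

__all__ = ["FitResult", "implied_covariance", "discrepancy", "fit", "start_values"]


class SingularModelError(RuntimeError):
    pass


def _inv_i_minus_b(model: MatrixModel, beta: np.ndarray) -> np.ndarray:
    m = beta.shape[0]
    a = np.eye(m) - beta
    if abs(np.linalg.det(a)) < 1e-12:
        loops = _loop_report(model, beta)
        raise SingularModelError(
            "(I - B) is singular; the structural system has no unique reduced form."
            + (f" Offending loop(s): {loops}" if loops else "")
        )
    return np.linalg.inv(a)


def _loop_report(model: MatrixModel, beta: np.ndarray) -> str:
    import networkx as nx

    g = nx.DiGraph()
    rows, cols = np.nonzero(beta)
    for i, j in zip(rows, cols):
        g.add_edge(model.latent_names[j], model.latent_names[i])
    cycles = list(nx.simple_cycles(g))
    return "; ".join(" -> ".join(c + [c[0]]) for c in cycles[:5])


def implied_covariance(theta: np.ndarray, model: MatrixModel) -> np.ndarray:
    """Model-implied covariance Sigma(theta) of the observed variables."""
    beta = model.beta(theta)
    psi = model.psi(theta)
    a = _inv_i_minus_b(model, beta)
    lam_a = model.lambda_matrix @ a
    sigma = lam_a @ psi @ lam_a.T + model.theta_matrix
    return 0.5 * (sigma + sigma.T)


def discrepancy(s: np.ndarray, sigma: np.ndarray) -> float:
    """ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p (>= 0)."""
    s = np.asarray(s, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = s.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(s)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("discrepancy requires positive-definite matrices")
    return float(logdet_m + np.trace(s @ np.linalg.inv(sigma)) - logdet_s - p)


def start_values(model: MatrixModel, s: np.ndarray | None = None) -> np.ndarray:
    """Start vector for the free parameters.

    Indicatorless latents (item true scores, control constructs) start at the
    corresponding observed variances (minus their fixed error share) and
    covariances; free effects start at a small nonzero value.  These starts
    were baked in when the model was built against its sample moments, so
    this simply assembles the vector and checks it yields a finite F.
    """
    theta0 = model.start_vector()
    # fall back to scaled defaults if the stored starts are unusable
    try:
        sigma0 = implied_covariance(theta0, model)
        if not np.all(np.isfinite(sigma0)):
            raise FloatingPointError
    except Exception:
        theta0 = np.where(np.isfinite(theta0), theta0, 0.05)
    return theta0


# -- analytic derivatives ----------------------------------------------------


def _dsigma_stack(model: MatrixModel, theta: np.ndarray, params=None) -> np.ndarray:
    """Stack of dSigma/dtheta_k (q x p x p) at theta for the given parameters."""
    params = model.free if params is None else params
    beta = model.beta(theta)
    psi = model.psi(theta)
    a = _inv_i_minus_b(model, beta)
    mmat = model.lambda_matrix @ a            # p x m
    kmat = a @ psi @ mmat.T                   # m x p
    p = model.p
    out = np.zeros((len(params), p, p))
    for k, f in enumerate(params):
        d = out[k]
        for mat, i, j in f.loci:
            if mat == "B":
                block = np.outer(mmat[:, i], kmat[j, :])
                d += block + block.T
            else:
                if i == j:
                    d += np.outer(mmat[:, i], mmat[:, i])
                else:
                    block = np.outer(mmat[:, i], mmat[:, j])
                    d += block + block.T
    return out


def _grad_and_info(
    model: MatrixModel,
    theta: np.ndarray,
    s: np.ndarray,
    params=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of F and expected information E_kl = tr(Sig^-1 dSig_k Sig^-1 dSig_l)."""
    sigma = implied_covariance(theta, model)
    sigma_inv = np.linalg.inv(sigma)
    w = sigma_inv - sigma_inv @ s @ sigma_inv
    dsig = _dsigma_stack(model, theta, params)
    grad = np.einsum("ij,kji->k", w, dsig)
    u = np.einsum("ij,kjl,lm->kim", sigma_inv, dsig, sigma_inv)
    info = np.einsum("kij,lji->kl", u, dsig)
    return grad, info


def gradient(model: MatrixModel, theta: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Analytic gradient of the ML discrepancy at theta."""
    return _grad_and_info(model, theta, s)[0]


# -- fitting -----------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and fit statistics from one covariance-structure ML fit."""

    model: MatrixModel
    moments: SampleMoments
    theta_hat: np.ndarray
    f_min: float
    chi_square: float
    df: int
    p_value: float
    implied_sigma: np.ndarray
    std_errors: np.ndarray
    converged: bool
    n_iter: int
    gradient_norm: float
    chi2_multiplier: str = "n-1"
    warnings: list[str] = field(default_factory=list)

    @property
    def param_names(self) -> list[str]:
        return [f.name for f in self.model.free]

    @property
    def significant(self) -> np.ndarray:
        """Flag per parameter: |estimate| exceeds two standard errors."""
        with np.errstate(invalid="ignore"):
            return np.abs(self.theta_hat) > 2.0 * self.std_errors

    def estimate(self, name: str) -> float:
        return float(self.theta_hat[self.param_names.index(name)])

    def coefficient(self, source: str, target: str) -> float:
        """Structural coefficient source -> target (free or fixed)."""
        from .model import PathSpec, _infer_klass

        path = PathSpec(source, target)
        path = type(path)(source, target, klass=_infer_klass(self.model.spec, path))
        mat, i, j = self.model.path_locus(path)
        b = self.model.beta(self.theta_hat)
        return float(b[i, j]) if mat == "B" else float(self.model.psi(self.theta_hat)[i, j])

    def latent_covariance(self) -> np.ndarray:
        beta = self.model.beta(self.theta_hat)
        psi = self.model.psi(self.theta_hat)
        a = _inv_i_minus_b(self.model, beta)
        return a @ psi @ a.T

    def r_squared(self) -> dict[str, float]:
        """R^2 of each endogenous latent (scale and downstream constructs).

        The scale's R^2 is 1.0 by construction whenever its residual variance
        is fixed at zero: the producing equation leaves nothing unexplained.
        """
        cov = self.latent_covariance()
        psi = self.model.psi(self.theta_hat)
        out = {}
        spec = self.model.spec
        names = [spec.scale.name] + [f"{d}(LV)" for d in spec.downstream]
        for nm in names:
            i = self.model.index[nm]
            v = cov[i, i]
            out[nm] = float(1.0 - psi[i, i] / v) if v > 0 else np.nan
        return out

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for f, est, se, sig in zip(
            self.model.free, self.theta_hat, self.std_errors, self.significant
        ):
            rows.append(
                {
                    "parameter": f.name,
                    "class": f.klass,
                    "estimate": est,
                    "std_error": se,
                    "significant": bool(sig),
                }
            )
        return pd.DataFrame(rows)


def _penalized_f(model: MatrixModel, theta: np.ndarray, s: np.ndarray) -> float:
    """F(theta), +inf when Sigma (or the reduced form) is not usable."""
    try:
        sigma = implied_covariance(theta, model)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            return np.inf
        sign_s, logdet_s = np.linalg.slogdet(s)
        return float(
            logdet + np.trace(s @ np.linalg.inv(sigma)) - logdet_s - s.shape[0]
        )
    except (SingularModelError, np.linalg.LinAlgError, FloatingPointError):
        return np.inf


def fit(
    model: MatrixModel,
    moments: SampleMoments,
    *,
    chi2_multiplier: str = "n-1",
    se: str = "expected",
    max_iter: int = 300,
    gtol: float = 1e-6,
    ftol: float = 1e-9,
) -> FitResult:
    """Fit the model to sample moments by Fisher-scoring ML.

    ``chi2_multiplier``: ``"n-1"`` (classic convention) or ``"n"``.
    ``se``: ``"expected"`` information (default) or ``"observed"``
    (finite differences of the analytic gradient).
    """
    from .model import degrees_of_freedom

    mom = moments.reorder(model.obs_names)
    s = mom.s_matrix
    n = mom.n_obs
    mult = {"n-1": n - 1, "n": n}[chi2_multiplier]

    theta = start_values(model, s).astype(float)
    f_val = _penalized_f(model, theta, s)
    if not np.isfinite(f_val):
        # shrink exogenous covariances toward 0 until the start is feasible
        for shrink in (0.5, 0.25, 0.1, 0.0):
            trial = theta.copy()
            for k, fp in enumerate(model.free):
                if fp.klass in ("exog_cov", "disturbance_cov"):
                    trial[k] *= shrink
            f_trial = _penalized_f(model, trial, s)
            if np.isfinite(f_trial):
                theta, f_val = trial, f_trial
                break
    if not np.isfinite(f_val):
        raise SingularModelError("no feasible start values found")

    warnings: list[str] = list(model.warnings)
    converged = False
    gnorm = np.inf
    ridge = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        grad, info = _grad_and_info(model, theta, s)
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < gtol:
            converged = True
            break
        # Fisher-scoring direction with Levenberg safeguard
        scale = float(np.mean(np.diag(info))) or 1.0
        step = None
        lam = ridge
        for _ in range(12):
            try:
                step = -linalg.solve(
                    info + (lam + 1e-10) * scale * np.eye(len(theta)),
                    grad,
                    assume_a="pos",
                )
                break
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6)
        if step is None:
            warnings.append("information matrix unusable; stopping")
            break
        # backtracking line search; shrink through non-PD trial Sigmas
        alpha = 1.0
        accepted = False
        while alpha > 1e-12:
            trial = theta + alpha * step
            f_trial = _penalized_f(model, trial, s)
            if np.isfinite(f_trial) and f_trial < f_val - 1e-14:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if lam < 1e6:
                ridge = max(lam * 10.0, 1e-6)
                continue
            break
        ridge = lam / 10.0 if lam > 0 else 0.0
        rel_drop = (f_val - f_trial) / max(abs(f_val), 1e-12)
        theta, f_val = trial, f_trial
        if rel_drop < ftol:
            grad, _ = _grad_and_info(model, theta, s)
            gnorm = float(np.max(np.abs(grad)))
            converged = gnorm < max(gtol, 1e-4)
            break

    grad, info = _grad_and_info(model, theta, s)
    gnorm = float(np.max(np.abs(grad)))
    if not converged and gnorm < max(gtol, 1e-4):
        converged = True
    if not converged:
        warnings.append(
            f"optimizer did not converge: max|grad| = {gnorm:.3g} after {it} iterations"
        )

    # standard errors
    if se == "observed":
        hess = _numeric_hessian(model, theta, s)
    else:
        hess = info
    std = np.full(len(theta), np.nan)
    try:
        cov_theta = (2.0 / mult) * np.linalg.inv(hess)
        diag = np.diag(cov_theta)
        std = np.sqrt(np.where(diag > 0, diag, np.nan))
        if np.any(diag <= 0):
            warnings.append("non-positive variance in the inverse information matrix")
    except np.linalg.LinAlgError:
        warnings.append("information matrix singular at the optimum; no standard errors")

    # Heywood diagnostics: negative free variances are flagged, not bounded
    for k, fp in enumerate(model.free):
        if fp.klass in ("exog_var", "disturbance", "scale_residual") and theta[k] < 0:
            warnings.append(f"Heywood case: variance {fp.name} = {theta[k]:.4g} < 0")

    df = degrees_of_freedom(model)
    chi2 = mult * f_val
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return FitResult(
        model=model,
        moments=mom,
        theta_hat=theta,
        f_min=f_val,
        chi_square=float(chi2),
        df=df,
        p_value=p_value,
        implied_sigma=implied_covariance(theta, model),
        std_errors=std,
        converged=converged,
        n_iter=it,
        gradient_norm=gnorm,
        chi2_multiplier=chi2_multiplier,
        warnings=warnings,
    )


def _numeric_hessian(model: MatrixModel, theta: np.ndarray, s: np.ndarray) -> np.ndarray:
    q = len(theta)
    hess = np.zeros((q, q))
    h = 1e-5
    for k in range(q):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        gp = gradient(model, tp, s)
        gm = gradient(model, tm, s)
        hess[:, k] = (gp - gm) / (2 * h)
    return 0.5 * (hess + hess.T)
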