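"""Economically consistent food-demand system.

The demand side of the model is a matrix of uncompensated (Marshallian)
price elasticities ``eps`` together with income elasticities ``eta`` and
budget shares ``w``.  Raw elasticity priors rarely satisfy the adding-up
restrictions of consumer theory, so they are calibrated to obey

* Engel aggregation:    sum_i w_i * eta_i = 1
* Cournot aggregation:  sum_i w_i * eps_ij = -w_j   for every price j

either by a weighted least-squares projection (the exact KKT linear system)
or by a generalized maximum-entropy (GME) reparameterization on three
support points per coefficient.  Demand responses to price changes are
log-linear: ``q_i' = q_i * exp(sum_j eps_ij * dlnp_j)``; because the
elasticities are uncompensated, income effects are embedded and no separate
income term appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ElasticityMatrix",
    "check_aggregation",
    "calibrate_elasticities",
    "demand_response",
    "energy_and_mass_changes",
]

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class ElasticityMatrix:
    """Uncompensated elasticity matrix for one country.

    Attributes
    ----------
    eps:
        (n, n) matrix; ``eps[i, j]`` is the elasticity of demand for good i
        with respect to the price of good j.
    eta:
        (n,) income elasticities.
    w:
        (n,) budget shares, strictly positive and summing to one.
    group_ids:
        Ordered food-group labels, length n.
    """

    eps: np.ndarray
    eta: np.ndarray
    w: np.ndarray
    group_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        eta = np.asarray(self.eta, dtype=float).ravel()
        w = np.asarray(self.w, dtype=float).ravel()
        n = w.size
        if eps.shape != (n, n) or eta.size != n:
            raise ValueError(
                f"inconsistent dimensions: eps {eps.shape}, eta {eta.size}, w {n}"
            )
        if np.any(w <= 0):
            raise ValueError("budget shares must be strictly positive")
        if abs(w.sum() - 1.0) > _SHARE_TOL:
            raise ValueError(f"budget shares sum to {w.sum():.12f}, expected 1")
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "w", w)
        if self.group_ids is None:
            object.__setattr__(self, "group_ids", tuple(f"g{i}" for i in range(n)))
        elif len(self.group_ids) != n:
            raise ValueError("group_ids length does not match n")
        else:
            object.__setattr__(self, "group_ids", tuple(self.group_ids))

    @property
    def n(self) -> int:
        return self.w.size


def check_aggregation(E: ElasticityMatrix) -> tuple[float, np.ndarray]:
    """Residuals of the Engel and Cournot aggregation conditions.

    Returns ``(engel, cournot)`` with ``engel = sum_i w_i eta_i - 1`` and
    ``cournot[j] = sum_i w_i eps_ij + w_j``; both are zero for a consistent
    system.
    """
    engel = float(E.w @ E.eta - 1.0)
    cournot = E.w @ E.eps + E.w
    return engel, cournot


def _constraint_system(
    E: ElasticityMatrix, homogeneity: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the adding-up restrictions as A x = b over x = [vec(eps), eta]."""
    n = E.n
    nvar = n * n + n
    rows = 1 + n + (n if homogeneity else 0)
    A = np.zeros((rows, nvar))
    b = np.zeros(rows)
    A[0, n * n :] = E.w  # Engel
    b[0] = 1.0
    for j in range(n):  # Cournot, one row per price
        A[1 + j, j : n * n : n] = E.w
        b[1 + j] = -E.w[j]
    if homogeneity:  # sum_j eps_ij + eta_i = 0
        for i in range(n):
            r = 1 + n + i
            A[r, i * n : (i + 1) * n] = 1.0
            A[r, n * n + i] = 1.0
    return A, b


def _projection(
    prior: ElasticityMatrix,
    sigma: np.ndarray,
    homogeneity: bool,
) -> np.ndarray:
    """Solve min sum ((x - xhat)/sigma)^2 s.t. A x = b via the KKT system."""
    n = prior.n
    x_hat = np.concatenate([prior.eps.ravel(), prior.eta])
    A, b = _constraint_system(prior, homogeneity)
    m, nvar = A.shape
    K = np.zeros((nvar + m, nvar + m))
    K[:nvar, :nvar] = np.diag(2.0 / sigma**2)
    K[:nvar, nvar:] = A.T
    K[nvar:, :nvar] = A
    rhs = np.concatenate([2.0 * x_hat / sigma**2, b])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular KKT system in projection calibration") from exc
    return sol[:nvar]


def _gme(
    prior: ElasticityMatrix,
    sigma: np.ndarray,
    homogeneity: bool,
    support_width: float = 3.0,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> np.ndarray:
    """Cross-entropy (GME) calibration via the exact dual.

    Each coefficient v is re-parameterized as the mean of a 3-point
    distribution on supports ``xhat_v + {-width, 0, +width} * sigma_v`` with
    a uniform (prior-centred) reference distribution.  Minimizing the
    cross-entropy to the reference subject to the linear restrictions gives
    exponential-family posteriors ``p_vk ∝ exp(-theta_v s_vk)`` with
    ``theta = A.T @ lam``; the (n+1)-dimensional dual is smooth and convex
    and is solved by damped Newton iterations.
    """
    x_hat = np.concatenate([prior.eps.ravel(), prior.eta])
    A, b = _constraint_system(prior, homogeneity)
    m, nvar = A.shape
    # supports: (nvar, 3)
    S = x_hat[:, None] + np.array([-1.0, 0.0, 1.0]) * (support_width * sigma[:, None])

    # feasibility: for each constraint the attainable range of A @ x
    lo = np.where(A > 0, A * S[:, 0][None, :], A * S[:, -1][None, :]).sum(axis=1)
    hi = np.where(A > 0, A * S[:, -1][None, :], A * S[:, 0][None, :]).sum(axis=1)
    bad = (b < lo - 1e-12) | (b > hi + 1e-12)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            "GME support bounds infeasible for constraint "
            f"{idx} (need {b[idx]:.4g} in [{lo[idx]:.4g}, {hi[idx]:.4g}]); "
            "widen the support (increase support_width or sigma)"
        )

    lam = np.zeros(m)

    def moments(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = A.T @ lam
        z = -theta[:, None] * S
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        mean = (p * S).sum(axis=1)
        var = (p * S**2).sum(axis=1) - mean**2
        return mean, var

    for _ in range(max_iter):
        mean, var = moments(lam)
        grad = b - A @ mean  # gradient of the dual potential
        if np.linalg.norm(grad, ord=np.inf) < tol:
            break
        H = (A * var[None, :]) @ A.T  # dual Hessian (PSD)
        H[np.diag_indices_from(H)] += 1e-14
        step = np.linalg.solve(H, grad)
        # damped update: backtrack on the dual objective's directional test
        t = 1.0
        g0 = np.linalg.norm(grad)
        for _ in range(60):
            mean_t, _ = moments(lam - t * step)
            if np.linalg.norm(b - A @ mean_t) <= g0 * (1.0 - 1e-4 * t) or t < 1e-12:
                break
            t *= 0.5
        lam = lam - t * step
    else:
        raise ValueError(
            "GME calibration did not converge; the restrictions may be at the "
            "edge of the support — widen the support bounds"
        )
    mean, _ = moments(lam)
    return mean


def calibrate_elasticities(
    prior: ElasticityMatrix,
    method: str = "projection",
    sigma_eps: np.ndarray | None = None,
    sigma_eta: np.ndarray | None = None,
    homogeneity: bool = False,
    support_width: float = 3.0,
) -> ElasticityMatrix:
    """Calibrate an elasticity prior to satisfy Engel and Cournot aggregation.

    Parameters
    ----------
    prior:
        Elasticity prior with valid budget shares.
    method:
        ``"projection"`` — exact equality-constrained weighted least squares
        via the KKT linear system; ``"gme"`` — generalized maximum entropy on
        3 support points per coefficient spanning prior ± ``support_width``
        standard deviations.
    sigma_eps, sigma_eta:
        Prior uncertainty weights (default 1 everywhere).
    homogeneity:
        Additionally impose ``sum_j eps_ij + eta_i = 0`` (off by default).

    Returns
    -------
    ElasticityMatrix
        Satisfies both aggregation conditions to better than 1e-8.
    """
    n = prior.n
    se = np.ones((n, n)) if sigma_eps is None else np.asarray(sigma_eps, float)
    sh = np.ones(n) if sigma_eta is None else np.asarray(sigma_eta, float)
    if se.shape != (n, n) or sh.shape != (n,):
        raise ValueError("sigma_eps must be (n, n) and sigma_eta (n,)")
    if np.any(se <= 0) or np.any(sh <= 0):
        raise ValueError("uncertainty weights must be strictly positive")
    sigma = np.concatenate([se.ravel(), sh])

    if method == "projection":
        x = _projection(prior, sigma, homogeneity)
    elif method == "gme":
        x = _gme(prior, sigma, homogeneity, support_width=support_width)
    else:
        raise ValueError(f"unknown method {method!r}; use 'projection' or 'gme'")

    out = replace(
        prior, eps=x[: n * n].reshape(n, n), eta=x[n * n :], group_ids=prior.group_ids
    )
    engel, cournot = check_aggregation(out)
    resid = max(abs(engel), float(np.abs(cournot).max()))
    if resid > 1e-8:
        raise ValueError(f"calibration left residual {resid:.2e} > 1e-8")
    return out


def demand_response(
    q: np.ndarray,
    dlnp: np.ndarray,
    E: ElasticityMatrix,
    form: str = "loglinear",
) -> np.ndarray:
    """Demand after a vector of log consumer-price changes.

    The default log-linear form ``q_i' = q_i * exp((eps @ dlnp)_i)`` is exact
    under constant elasticities and keeps demand positive; ``form="linear"``
    gives the first-order form ``q_i * (1 + (eps @ dlnp)_i)``.
    """
    q = np.asarray(q, dtype=float)
    dlnp = np.asarray(dlnp, dtype=float)
    if q.shape != (E.n,) or dlnp.shape != (E.n,):
        raise ValueError("q and dlnp must be length-n vectors")
    if np.any(q < 0):
        raise ValueError("demand must be >= 0")
    if not np.all(np.isfinite(dlnp)):
        raise ValueError("dlnp must be finite")
    growth = E.eps @ dlnp
    if form == "loglinear":
        return q * np.exp(growth)
    if form == "linear":
        return q * (1.0 + growth)
    raise ValueError(f"unknown form {form!r}")


def energy_and_mass_changes(
    q_base: np.ndarray,
    q_scen: np.ndarray,
    kcal_per_g: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-group mass change (g d^-1) and total energy change (kcal d^-1)."""
    q_base = np.asarray(q_base, dtype=float)
    q_scen = np.asarray(q_scen, dtype=float)
    kcal = np.asarray(kcal_per_g, dtype=float)
    if not (q_base.shape == q_scen.shape == kcal.shape):
        raise ValueError("q_base, q_scen and kcal_per_g must have equal length")
    if np.any(kcal < 0):
        raise ValueError("energy densities must be >= 0")
    dmass = q_scen - q_base
    return dmass, float(kcal @ dmass)
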