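"""Additive-dominance G-BLUP: marker coding, genomic relationship matrices,
REML variance components, marker-effect backsolving and prediction.

Model
-----
``y = X b + u_a + u_d + e`` with ``u_a ~ N(0, Ga sigma2_a)``,
``u_d ~ N(0, Gd sigma2_d)``, ``e ~ N(0, I sigma2_e)`` and an
intercept-only ``X``.  The additive coding ``W`` takes values
``2 - 2p, 1 - 2p, -2p`` and the dominance coding ``S`` takes
``-2q^2, 2pq, -2p^2`` for dosages 2, 1, 0 (q = 1 - p), so both are
column-centred when ``p`` is the observed training frequency.  The
relationship matrices are ``Ga = W W' / sum 2 p q`` and
``Gd = S S' / sum (2 p q)^2``, with monomorphic markers zero-coded and
excluded from the denominators.

The equivalent marker-level (ridge / RR-BLUP) model has effects
``m_a ~ N(0, I sigma2_a / sum 2pq)`` and ``m_d ~ N(0, I sigma2_d /
sum (2pq)^2)``; predictions through either route are identical, which the
test-suite asserts against a direct mixed-model-equation solve.

Variance components are estimated by REML: EM updates (monotone in the
restricted likelihood, the reference algorithm) or average-information (AI)
updates with EM fallback for speed on large training sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

from .errors import (DegenerateDataError, InvalidConfigurationError,
                     UndefinedReliabilityError)

__all__ = [
    "VarianceComponents",
    "MarkerModel",
    "code_markers",
    "grm_denominators",
    "build_grm",
    "reml_fit",
    "solve_effects",
    "gblup_genomic_values",
    "fit",
    "predict",
    "reliability",
]


def _check_dosages(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages)
    if not np.isin(d, (0, 1, 2)).all():
        raise InvalidConfigurationError("marker dosages must be 0, 1 or 2")
    return d.astype(float)


def code_markers(dosages: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive (W) and dominance (S) codings of a dosage matrix.

    Markers fixed at the supplied frequencies (p = 0 or 1) yield all-zero
    columns in both matrices.
    """
    d = _check_dosages(dosages)
    p = np.asarray(freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidConfigurationError("allele frequencies must lie in [0, 1]")
    q = 1.0 - p
    poly = (p > 0) & (p < 1)
    W = (d - 2.0 * p) * poly
    S = np.where(d == 1, 2.0 * p * q,
                 np.where(d == 2, -2.0 * q ** 2, -2.0 * p ** 2)) * poly
    return W, S


def grm_denominators(freqs: np.ndarray) -> tuple[float, float]:
    """(sum 2pq, sum (2pq)^2) over polymorphic markers."""
    p = np.asarray(freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateDataError("all markers are monomorphic")
    h = 2.0 * p[poly] * (1.0 - p[poly])
    return float(h.sum()), float((h ** 2).sum())


def build_grm(W: np.ndarray, S: np.ndarray,
              freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive and dominance genomic relationship matrices."""
    da, dd = grm_denominators(freqs)
    return (W @ W.T) / da, (S @ S.T) / dd


@dataclass
class VarianceComponents:
    """REML estimates for the additive-dominance model."""

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    converged: bool = True
    n_iterations: int = 0
    method: str = "em"
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_e


def reml_fit(phenotypes: np.ndarray, Ga: np.ndarray, Gd: np.ndarray,
             tol: float = 1e-6, max_iter: int = 500, method: str = "em",
             init: tuple[float, float, float] | None = None) -> VarianceComponents:
    """Estimate (sigma2_a, sigma2_d, sigma2_e) by REML.

    ``method="em"`` uses expectation-maximisation updates whose restricted
    log-likelihood is non-decreasing at every iteration; ``method="ai"``
    uses average-information steps (quadratic convergence) and falls back
    to an EM step whenever an AI step would reduce the likelihood.
    Components are floored at ``1e-8 * var(y)``; convergence is declared
    when the largest parameter change, relative to the total variance,
    drops below ``tol``.  Non-convergence at ``max_iter`` is flagged in the
    result, not fatal.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = y.shape[0]
    if Ga.shape != (n, n) or Gd.shape != (n, n):
        raise InvalidConfigurationError("GRM order must match phenotype length")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise DegenerateDataError("phenotypes have zero variance")
    if method not in ("em", "ai"):
        raise InvalidConfigurationError(f"unknown REML method {method!r}")
    floor = 1e-8 * vary
    theta = np.array(init if init is not None
                     else (0.3 * vary, 0.1 * vary, 0.6 * vary), dtype=float)
    theta = np.maximum(theta, floor)
    eye = np.eye(n)
    ones = np.ones(n)
    trace: list[float] = []
    converged = False
    # previous accepted state, for the optimistic-AI fallback
    prev_em_theta: np.ndarray | None = None
    prev_ll = -np.inf
    last_step = "em"
    n_reverts = 0
    ai_paused_until = 0

    for it in range(1, max_iter + 1):
        V = theta[0] * Ga + theta[1] * Gd + theta[2] * eye
        c, low = cho_factor(V, lower=True)
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        Vinv, info = dpotri(c, lower=1)
        if info != 0:  # pragma: no cover - Cholesky already succeeded
            raise np.linalg.LinAlgError("dpotri failed")
        Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
        vrow = Vinv @ ones
        s = vrow.sum()
        P = Vinv - np.outer(vrow, vrow) / s
        Py = P @ y
        ll = -0.5 * (logdet_v + np.log(s) + y @ Py)

        # optimistic AI: accept the step, but if it lowered the likelihood
        # retreat to the EM update from the previous point (monotone)
        if (last_step == "ai" and prev_em_theta is not None
                and ll < prev_ll - 1e-10):
            theta = prev_em_theta
            last_step = "em"
            n_reverts += 1
            if n_reverts >= 3:  # persistent oscillation: cool off on EM
                ai_paused_until = it + 10
            continue
        trace.append(ll)

        tr_pga = float((P * Ga).sum())
        tr_pgd = float((P * Gd).sum())
        tr_p = float(np.trace(P))
        ga_py = Ga @ Py
        gd_py = Gd @ Py
        quad = np.array([Py @ ga_py, Py @ gd_py, Py @ Py])
        trs = np.array([tr_pga, tr_pgd, tr_p])

        em_theta = np.maximum(theta + theta ** 2 * (quad - trs) / n, floor)
        new_theta, last_step = em_theta, "em"
        if method == "ai" and it >= ai_paused_until:
            score = -0.5 * (trs - quad)
            # components pinned at the floor with a downhill gradient are
            # held there; AI solves over the free components only
            free = ~((theta <= floor * (1 + 1e-6)) & (score < 0))
            t = np.stack([ga_py, gd_py, Py])  # (3, n)
            Pt = t @ P
            ai = 0.5 * (Pt @ t.T)
            if free.any():
                try:
                    delta = np.linalg.solve(ai[np.ix_(free, free)],
                                            score[free])
                    if np.all(np.isfinite(delta)):
                        cand = theta.copy()
                        cand[free] = theta[free] + delta
                        new_theta = np.maximum(cand, floor)
                        last_step = "ai"
                except np.linalg.LinAlgError:
                    pass

        change = float(np.max(np.abs(new_theta - theta))) / max(theta.sum(), floor)
        prev_em_theta, prev_ll = em_theta, ll
        theta = new_theta
        if change < tol:
            converged = True
            break

    return VarianceComponents(float(theta[0]), float(theta[1]), float(theta[2]),
                              converged=converged, n_iterations=it,
                              method=method, loglik_trace=np.asarray(trace))


@dataclass
class MarkerModel:
    """A fitted additive-dominance marker model.

    Stores everything needed to predict new individuals: per-marker
    additive and dominance effects, the training allele frequencies used
    for coding, the intercept and the variance components.
    """

    intercept: float
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    training_freqs: np.ndarray
    variance_components: VarianceComponents
    n_training: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return self.training_freqs.shape[0]

    def predict(self, dosages: np.ndarray) -> np.ndarray:
        return predict(self, dosages)


def solve_effects(phenotypes: np.ndarray, W: np.ndarray, S: np.ndarray,
                  variance_components: VarianceComponents,
                  freqs: np.ndarray, solver: str = "covariance") -> MarkerModel:
    """Backsolve additive and dominance marker effects (RR-BLUP).

    ``solver="covariance"`` uses the identity ``m_a = sigma2_ma W' V^{-1}
    (y - X b)`` (and likewise for dominance), which is the marker-level
    mixed-model solution expressed through the phenotypic covariance
    matrix; ``solver="mme"`` assembles and solves the explicit ridge
    mixed-model equations, useful as an independent route on small data.
    """
    y = np.asarray(phenotypes, dtype=float)
    n, m = W.shape
    vc = variance_components
    da, dd = grm_denominators(freqs)
    s2ma = vc.sigma2_a / da
    s2md = vc.sigma2_d / dd

    if solver == "covariance":
        V = s2ma * (W @ W.T) + s2md * (S @ S.T) + vc.sigma2_e * np.eye(n)
        c, low = cho_factor(V, lower=True)
        v1 = cho_solve((c, low), np.ones(n))
        b = float(v1 @ y / v1.sum())
        r = cho_solve((c, low), y - b)
        ma = s2ma * (W.T @ r)
        md = s2md * (S.T @ r)
    elif solver == "mme":
        lam_a = vc.sigma2_e / s2ma
        lam_d = vc.sigma2_e / s2md
        X = np.ones((n, 1))
        Z = np.hstack([W, S])
        C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z]])
        C[1:m + 1, 1:m + 1] += lam_a * np.eye(m)
        C[m + 1:, m + 1:] += lam_d * np.eye(m)
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(C, rhs)
        b = float(sol[0])
        ma = sol[1:m + 1]
        md = sol[m + 1:]
    else:
        raise InvalidConfigurationError(f"unknown solver {solver!r}")

    return MarkerModel(b, ma, md, np.asarray(freqs, dtype=float), vc, n,
                       metadata={"solver": solver,
                                 "sigma2_ma": s2ma, "sigma2_md": s2md})


def gblup_genomic_values(phenotypes: np.ndarray, Ga: np.ndarray,
                         Gd: np.ndarray,
                         variance_components: VarianceComponents) -> np.ndarray:
    """Total genomic values u_a + u_d via the relationship-matrix route."""
    y = np.asarray(phenotypes, dtype=float)
    n = y.shape[0]
    vc = variance_components
    V = vc.sigma2_a * Ga + vc.sigma2_d * Gd + vc.sigma2_e * np.eye(n)
    c, low = cho_factor(V, lower=True)
    v1 = cho_solve((c, low), np.ones(n))
    b = float(v1 @ y / v1.sum())
    r = cho_solve((c, low), y - b)
    return (vc.sigma2_a * Ga + vc.sigma2_d * Gd) @ r


def fit(phenotypes: np.ndarray, dosages: np.ndarray,
        freqs: np.ndarray | None = None, method: str = "em",
        tol: float = 1e-6, max_iter: int = 500) -> MarkerModel:
    """Convenience pipeline: code markers, build GRMs, REML, backsolve."""
    d = _check_dosages(dosages)
    p = d.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    W, S = code_markers(d, p)
    Ga, Gd = build_grm(W, S, p)
    vc = reml_fit(phenotypes, Ga, Gd, tol=tol, max_iter=max_iter, method=method)
    return solve_effects(phenotypes, W, S, vc, p)


def predict(model: MarkerModel, dosages: np.ndarray) -> np.ndarray:
    """Total genomic value W m_a + S m_d for new individuals.

    Validation genotypes are coded with the TRAINING allele frequencies,
    which is what makes marker-effect transfer across generations coherent.
    """
    d = np.asarray(dosages)
    if d.ndim != 2 or d.shape[1] != model.n_markers:
        raise InvalidConfigurationError(
            f"expected {model.n_markers} markers, got {d.shape}")
    Wv, Sv = code_markers(d, model.training_freqs)
    return Wv @ model.additive_effects + Sv @ model.dominance_effects


def reliability(predicted: np.ndarray, true_genetic_values: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and true values."""
    x = np.asarray(predicted, dtype=float)
    g = np.asarray(true_genetic_values, dtype=float)
    if x.shape != g.shape:
        raise InvalidConfigurationError("vectors must have equal length")
    if np.std(x) == 0 or np.std(g) == 0:
        raise UndefinedReliabilityError(
            "reliability is undefined for a constant vector")
    r = float(np.corrcoef(x, g)[0, 1])
    return r * r
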