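"""Sparse logistic regression with automatic relevance determination (ARD).

Second stage of the classifier.  A Bayesian logistic model

    p(y_n = 1 | x_n, w) = sigma(w' x_n),    w_j ~ N(0, 1/alpha_j)

with one precision hyperparameter alpha_j per weight.  Fitting alternates the
Jaakkola–Jordan variational bound updates

    lambda(xi) = tanh(xi/2) / (4 xi)
    S  = (A + 2 sum_n lambda(xi_n) x_n x_n')^{-1}
    m  = S sum_n (y_n - 1/2) x_n
    xi_n^2 = x_n' (S + m m') x_n
    alpha_j <- 1 / (m_j^2 + S_jj)

and prunes a feature once its precision exceeds a threshold (default 1e8):
the ARD mechanism drives the precisions of useless features to infinity, so
the surviving set is chosen by the data rather than by a tuned
hyperparameter.  The bias is an always-active weight with a tiny fixed
precision (effectively unpenalised), which matters under class imbalance.

Features are standardised internally on the training data (ARD precisions
are scale-sensitive); the transform is stored in the model and re-applied at
prediction time.

Two xi-update rules are available: the posterior rule above (default) and a
"mode" rule xi_n = |x_n' m| that ignores the posterior covariance.  With a
fixed common precision and the mode rule, the fixed point of the iteration
is exactly the ridge-penalised maximum a posteriori solution, which provides
an external cross-check of the optimiser against a Newton solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainOptions", "SLRModel", "SLRError", "slr_fit", "slr_predict", "decision"]


class SLRError(ValueError):
    pass


@dataclass
class TrainOptions:
    """Optimiser settings.

    ``alpha_rule`` selects the precision update: the variational-Bayes form
    1/(m_j^2 + S_jj) (default) shrinks smoothly and splits weight across
    correlated informative features; the MacKay evidence form gamma_j/m_j^2
    diverges geometrically for irrelevant features and behaves like greedy
    best-subset selection.  The two rules reach very different precision
    scales for useless features (linear vs geometric growth), so the prune
    threshold defaults per rule: 1e3 under "vb", 1e8 under "mackay".  Set
    ``prune_threshold`` explicitly to override.
    """

    prune_threshold: float | None = None
    tol: float = 1e-6
    max_iter: int = 500
    bias_precision: float = 1e-6
    ard: bool = True
    alpha0: float = 1.0           # initial (or, if ard=False, fixed) precision
    xi_rule: str = "posterior"    # "posterior" or "mode"
    alpha_rule: str = "vb"        # "vb" or "mackay"
    standardize: bool = True
    track_bound: bool = False     # record the variational bound per sweep

    def resolved_prune_threshold(self) -> float:
        if self.prune_threshold is not None:
            return self.prune_threshold
        return 1e3 if self.alpha_rule == "vb" else 1e8

    def validate(self) -> None:
        if self.prune_threshold is not None and self.prune_threshold <= 0:
            raise SLRError("prune_threshold must be positive")
        if min(self.tol, self.bias_precision, self.alpha0) <= 0:
            raise SLRError("all train options must be positive")
        if self.max_iter < 1:
            raise SLRError("max_iter must be >= 1")
        if self.xi_rule not in ("posterior", "mode"):
            raise SLRError(f"unknown xi_rule {self.xi_rule!r}")
        if self.alpha_rule not in ("mackay", "vb"):
            raise SLRError(f"unknown alpha_rule {self.alpha_rule!r}")


@dataclass
class SLRModel:
    """Fitted ARD logistic model restricted to its surviving feature set.

    ``feature_ids`` indexes columns of the training matrix; the bias is the
    final entry of ``m`` / ``alpha`` and has no feature id.
    """

    feature_ids: np.ndarray       # surviving input-column indices
    m: np.ndarray                 # posterior mean over [active features, bias]
    S: np.ndarray                 # posterior covariance, same ordering
    alpha: np.ndarray             # ARD precisions, same ordering
    xi: np.ndarray                # per-subject variational parameters
    mean_: np.ndarray             # training standardisation (full input width)
    scale_: np.ndarray
    converged: bool
    n_iter: int
    bound_trace: list = field(default_factory=list)
    prune_iterations: list = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        """Weights of the surviving features (bias excluded), standardised scale."""
        return self.m[:-1]

    @property
    def bias(self) -> float:
        return float(self.m[-1])


def _lambda_jj(xi: np.ndarray) -> np.ndarray:
    """tanh(xi/2)/(4 xi), with the xi -> 0 limit 1/8."""
    xi = np.abs(xi)
    out = np.full_like(xi, 0.125)
    nz = xi > 1e-12
    out[nz] = np.tanh(xi[nz] / 2.0) / (4.0 * xi[nz])
    return out


def _bound(Xa, y, m, S, alpha, xi) -> float:
    """Jaakkola–Jordan marginal-likelihood lower bound at the current state."""
    lam = _lambda_jj(xi)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    val = float(
        np.sum(np.log(_sigmoid(xi)) - xi / 2.0 + lam * xi**2)
        + 0.5 * logdet_S
        + 0.5 * np.sum(np.log(alpha))
        + 0.5 * m @ np.linalg.solve(S, m)
    )
    return val


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _sweep_kernel(Xact, b_act, alpha, xi, ard, mackay, posterior_xi,
                  prune_at, bias_precision, tol, budget, m_prev, first):
    """Run bound-update sweeps on the current active set.

    Mirrors the pure-python loop in :func:`slr_fit` exactly; returns on a
    prune event (status 2), convergence (1) or an exhausted budget (0) so
    the caller can rebuild the active set.  The bias is the last column.
    """
    n, pa = Xact.shape
    S = np.eye(pa)
    m = m_prev.copy()
    delta = np.inf
    used = 0
    status = 0
    for t in range(budget):
        used = t + 1
        lam = np.empty(n)
        for i in range(n):
            x = abs(xi[i])
            lam[i] = 0.125 if x <= 1e-12 else np.tanh(x / 2.0) / (4.0 * x)
        H = (Xact * lam.reshape(n, 1)).T @ Xact * 2.0
        for j in range(pa):
            H[j, j] += alpha[j]
        S = np.linalg.inv(H)
        S = (S + S.T) / 2.0
        m_new = S @ b_act
        proj = Xact @ m_new
        if posterior_xi == 1:
            quad = np.sum((Xact @ S) * Xact, axis=1)
            xi = np.sqrt(np.maximum(quad + proj**2, 0.0))
        else:
            xi = np.abs(proj)

        if ard == 1:
            alpha_new = np.empty(pa)
            for j in range(pa):
                if mackay == 1:
                    gamma = 1.0 - alpha[j] * S[j, j]
                    mj2 = m_new[j] * m_new[j]
                    upd = gamma / mj2 if mj2 > 0 else np.inf
                    if not np.isfinite(upd) or upd <= 0:
                        upd = 2.0 * prune_at
                    alpha_new[j] = min(upd, 1e12)
                else:
                    alpha_new[j] = 1.0 / (m_new[j] * m_new[j] + S[j, j])
            alpha_new[pa - 1] = bias_precision     # bias never updated
            delta = 0.0
            for j in range(pa):
                d = abs(alpha_new[j] - alpha[j]) / alpha[j]
                if d > delta:
                    delta = d
            alpha = alpha_new
        else:
            if first == 0 or t > 0:
                delta = np.abs(m_new - m).max()
            else:
                delta = np.inf
        m = m_new

        if ard == 1:
            pruned = False
            for j in range(pa - 1):
                if alpha[j] > prune_at:
                    pruned = True
            if pruned:
                status = 2
                break
        if delta < tol:
            status = 1
            break
    return m, S, alpha, xi, used, status, delta


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def slr_fit(X: np.ndarray, y: np.ndarray, opts: TrainOptions | None = None) -> SLRModel:
    """Fit the ARD sparse logistic model.

    ``y`` must contain both classes.  Convergence is declared when the
    relative precision change max |d alpha| / alpha (or, with fixed
    precisions, the weight change) drops below ``opts.tol``; a fit that hits
    ``max_iter`` first is returned with ``converged=False``.
    """
    opts = opts or TrainOptions()
    opts.validate()
    prune_at = opts.resolved_prune_threshold()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise SLRError("X and y sizes differ")
    if not np.all(np.isfinite(X)):
        raise SLRError("features must be finite")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        if classes.size < 2:
            raise SLRError("both classes must be present in y")
        raise SLRError("labels must be coded 0/1")

    n, p = X.shape
    if opts.standardize:
        mean_, scale_ = X.mean(axis=0), X.std(axis=0)
        scale_ = np.where(scale_ > 0, scale_, 1.0)
    else:
        mean_, scale_ = np.zeros(p), np.ones(p)
    Xs = (X - mean_) / scale_
    Xa = np.column_stack([Xs, np.ones(n)])     # bias last

    # constant columns carry no information and would only stall the ARD
    # updates at their initial precision: drop them before iterating
    informative = X.std(axis=0) > 0
    active = np.append(np.flatnonzero(informative), p)  # indices into [features, bias]
    alpha = np.full(p + 1, opts.alpha0)
    alpha[-1] = opts.bias_precision
    xi = np.ones(n)
    m = np.zeros(p + 1)
    b_full = (y - 0.5) @ Xa                    # fixed linear term
    bound_trace: list[float] = []
    prune_iterations: list[int] = []
    converged = False

    use_kernel = _HAVE_NUMBA and not opts.track_bound
    Xact = Xa[:, active]
    it = -1
    if use_kernel:
        total = 0
        m_prev = np.zeros(active.size)
        first = True
        while total < opts.max_iter:
            (m_act, S, alpha_act, xi, used, status, delta) = _sweep_kernel(
                np.ascontiguousarray(Xact), np.ascontiguousarray(b_full[active]),
                np.ascontiguousarray(alpha[active]), xi,
                1 if opts.ard else 0,
                1 if opts.alpha_rule == "mackay" else 0,
                1 if opts.xi_rule == "posterior" else 0,
                prune_at, opts.bias_precision, opts.tol,
                opts.max_iter - total, m_prev, 1 if first else 0)
            total += used
            it = total - 1
            first = False
            alpha[active] = alpha_act
            m = np.zeros(p + 1)
            m[active] = m_act
            if status == 2:                       # prune event
                prune_iterations.append(it)
                keep = alpha_act <= prune_at
                keep[-1] = True                   # bias always active
                active = active[keep]
                Xact = Xa[:, active]
                m_prev = m_act[keep]
                if delta < opts.tol:
                    converged = True
                    break
            elif status == 1:
                converged = True
                break
            else:
                break
    else:
        for it in range(opts.max_iter):
            lam = _lambda_jj(xi)
            H = 2.0 * (Xact.T * lam) @ Xact
            H[np.diag_indices_from(H)] += alpha[active]
            S = np.linalg.inv(H)
            S = (S + S.T) / 2.0
            m_new = S @ b_full[active]

            proj = Xact @ m_new
            if opts.xi_rule == "posterior":
                xi = np.sqrt(np.maximum(
                    np.einsum("ij,jk,ik->i", Xact, S, Xact) + proj**2, 0.0))
            else:
                xi = np.abs(proj)

            if opts.ard:
                alpha_new = alpha.copy()
                if opts.alpha_rule == "mackay":
                    # evidence (type-II ML) update: gamma_j = 1 - alpha_j S_jj
                    # is the "well-determinedness" of weight j; useless
                    # features' precisions diverge geometrically
                    gamma = 1.0 - alpha[active] * np.diag(S)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        upd = gamma / m_new**2
                    upd = np.where(np.isfinite(upd) & (upd > 0), upd, 2 * prune_at)
                    alpha_new[active] = np.minimum(upd, 1e12)
                else:
                    alpha_new[active] = 1.0 / (m_new**2 + np.diag(S))
                alpha_new[active[-1]] = opts.bias_precision   # bias fixed
                delta = np.max(np.abs(alpha_new[active] - alpha[active])
                               / alpha[active])
                alpha = alpha_new
            else:
                delta = np.max(np.abs(m_new - m[active])) if it > 0 else np.inf

            m_full = np.zeros(p + 1)
            m_full[active] = m_new
            m = m_full
            if opts.track_bound:
                bound_trace.append(_bound(Xact, y, m_new, S, alpha[active], xi))

            if opts.ard:
                keep = alpha[active] <= prune_at
                keep[-1] = True                            # bias always active
                if not keep.all():
                    prune_iterations.append(it)
                    active = active[keep]
                    Xact = Xa[:, active]
            if delta < opts.tol:
                converged = True
                break

    # final state restricted to the active set
    lam = _lambda_jj(xi)
    H = 2.0 * (Xact.T * lam) @ Xact
    H[np.diag_indices_from(H)] += alpha[active]
    S = np.linalg.inv(H)
    S = (S + S.T) / 2.0
    m_act = S @ b_full[active]

    feat = active[:-1]
    return SLRModel(
        feature_ids=feat.copy(),
        m=np.append(m_act[:-1], m_act[-1]),
        S=S,
        alpha=alpha[active].copy(),
        xi=xi,
        mean_=mean_,
        scale_=scale_,
        converged=converged,
        n_iter=it + 1,
        bound_trace=bound_trace,
        prune_iterations=prune_iterations,
    )


def slr_predict(model: SLRModel, x: np.ndarray) -> np.ndarray | float:
    """Predictive probability of the positive (StD) class, sigma(m' x~).

    ``x`` may be one feature vector or a matrix of them, with the same column
    layout as the training matrix; the stored standardisation is re-applied
    and the surviving features plus bias are used.
    """
    x = np.asarray(x, dtype=float)
    one = x.ndim == 1
    X = x[None, :] if one else x
    if X.shape[1] != model.mean_.shape[0]:
        raise SLRError(
            f"expected {model.mean_.shape[0]} features, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise SLRError("missing/non-finite feature value")
    Xs = (X - model.mean_) / model.scale_
    z = Xs[:, model.feature_ids] @ model.m[:-1] + model.m[-1]
    p = _sigmoid(z)
    return float(p[0]) if one else p


def decision(model: SLRModel, x: np.ndarray, threshold: float = 0.5):
    """Class decision: "StD" iff predictive probability strictly exceeds the
    threshold (a probability of exactly 0.5 is called HC — ties go negative).

    At threshold 0.5 this is equivalent to the sign of the weighted linear
    summation m' x~.
    """
    p = slr_predict(model, x)
    if np.isscalar(p):
        return "StD" if p > threshold else "HC"
    return np.where(np.asarray(p) > threshold, "StD", "HC")
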