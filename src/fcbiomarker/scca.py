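"""L1-regularised sparse canonical correlation analysis (L1-SCCA).

First stage of the classifier: reduce the ~10^4-dimensional FC feature space
by finding sparse canonical pairs (u, v) maximising u' X' Y v subject to
||u||_2 <= 1, ||u||_1 <= c_u (and likewise for v), where X holds the FC
features and Y the subject attributes (diagnosis label plus nuisance
covariates such as age and sex).  Components whose attribute-side weight
vector v loads only on the diagnosis column — and not on any nuisance
covariate — carry diagnosis-specific FC structure; the union of their FC-side
supports, pooled over inner cross-validation folds and a grid of u-sparsity
bounds, is the candidate feature set handed to the sparse logistic stage.

The solver is the penalised-matrix-decomposition form of sparse CCA:
alternating soft-threshold-and-renormalise updates on M = X'Y, the L1 bound
enforced by bisection on the threshold, successive components obtained by
rank-one deflation of M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttributeMatrix",
    "SCCAComponent",
    "SCCAParams",
    "SCCAError",
    "soft_threshold",
    "l1_scca_fit",
    "diagnosis_only_components",
    "select_features",
    "build_attributes",
]


class SCCAError(ValueError):
    pass


@dataclass
class AttributeMatrix:
    """Centered subject-attribute matrix with per-column roles.

    Exactly one column carries the role "diagnosis"; the rest are "nuisance".
    """

    data: np.ndarray
    names: list
    roles: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SCCAError("attribute matrix must be 2-D")
        if len(self.names) != self.data.shape[1] or len(self.roles) != self.data.shape[1]:
            raise SCCAError("names/roles length mismatch")
        bad = set(self.roles) - {"diagnosis", "nuisance"}
        if bad:
            raise SCCAError(f"unknown roles: {bad}")
        if self.roles.count("diagnosis") < 1:
            raise SCCAError("need at least one diagnosis column")

    @property
    def diagnosis_cols(self) -> np.ndarray:
        return np.array([k for k, r in enumerate(self.roles) if r == "diagnosis"])

    @property
    def nuisance_cols(self) -> np.ndarray:
        return np.array([k for k, r in enumerate(self.roles) if r == "nuisance"],
                        dtype=int)


def build_attributes(y: np.ndarray, age: np.ndarray, sex: np.ndarray) -> AttributeMatrix:
    """Assemble the standard attribute matrix: diagnosis + (age, sex) nuisance.

    All columns are centred and scaled to unit variance (a constant column
    stays zero), so no attribute dominates the cross-product by scale alone.
    Sex is coded 1 = male, 0 = female before standardisation.
    """
    def std_col(c):
        c = np.asarray(c, dtype=float)
        c = c - c.mean()
        sd = c.std()
        return c / sd if sd > 0 else c

    cols = np.column_stack([std_col(y), std_col(age), std_col(sex)])
    return AttributeMatrix(cols, ["diagnosis", "age", "sex"],
                           ["diagnosis", "nuisance", "nuisance"])


@dataclass
class SCCAComponent:
    """One sparse canonical pair."""

    u: np.ndarray          # FC-side weights, ||u||_2 <= 1, ||u||_1 <= c_u
    v: np.ndarray          # attribute-side weights
    value: float           # singular value u' M v of the (deflated) cross-product
    correlation: float     # sample correlation of the canonical variates Xu, Yv

    def support(self, tol: float = 1e-10) -> np.ndarray:
        return np.flatnonzero(np.abs(self.u) > tol)


@dataclass
class SCCAParams:
    c_u_grid: tuple = (1.2, 1.6, 2.0, 2.5, 3.0)
    # c_v = 1 makes the attribute side exactly axis-aligned (one attribute per
    # component), giving the diagnosis-only rule its cleanest reading: a
    # component is kept iff its attribute is the diagnosis label.
    c_v: float = 1.0
    # None -> one component per attribute column: with the axis-aligned
    # attribute side, later components only redistribute deflation residue
    n_components: int | None = None
    max_iter: int = 100
    tol: float = 1e-8
    n_folds: int = 5
    seed: int = 0
    nonzero_tol: float = 1e-10

    def validate(self) -> None:
        if any(c < 1.0 for c in self.c_u_grid) or self.c_v < 1.0:
            raise SCCAError("L1 bounds must be >= 1 (else no unit-L2 vector is feasible)")
        if self.n_components is not None and self.n_components < 1:
            raise SCCAError("n_components must be >= 1")
        if self.n_folds < 2:
            raise SCCAError("n_folds must be >= 2")


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """sign(a) * max(|a| - delta, 0), elementwise."""
    if delta < 0:
        raise SCCAError(f"delta must be nonnegative, got {delta}")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


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
def _l1_project_kernel(w, c):
    """Closed-form soft-threshold-and-normalise; mirrors _l1_unit_project."""
    p = w.size
    peak = np.abs(w).max()
    out = np.zeros(p)
    if peak == 0.0:
        return out
    w = w / peak
    a = np.abs(w)
    norm = np.sqrt(np.sum(a * a))
    if np.sum(a) / norm <= c:
        return w / norm
    s = np.sort(a)[::-1]
    delta = -1.0
    Sk = 0.0
    Qk = 0.0
    for j in range(p):
        Sk += s[j]
        Qk += s[j] * s[j]
        b = s[j + 1] if j + 1 < p else 0.0
        kk = j + 1
        num = Sk - kk * b
        den2 = Qk - 2.0 * b * Sk + kk * b * b
        ratio = num / np.sqrt(den2) if den2 > 0 else np.inf
        if ratio >= c:
            A = kk * (kk - c * c)
            B = 2.0 * Sk * (c * c - kk)
            C = Sk * Sk - c * c * Qk
            if A != 0.0:
                disc = B * B - 4.0 * A * C
                if disc >= 0.0:
                    r = np.sqrt(disc)
                    for cand in ((-B + r) / (2.0 * A), (-B - r) / (2.0 * A)):
                        if b - 1e-12 <= cand <= s[j] + 1e-12:
                            delta = min(max(cand, b), s[j])
                            break
            break
    if delta >= 0.0:
        l1 = 0.0
        l2 = 0.0
        for j in range(p):
            v = a[j] - delta
            if v > 0:
                l1 += v
                l2 += v * v
        if l2 > 0 and l1 / np.sqrt(l2) <= c + 1e-6:
            nt = np.sqrt(l2)
            for j in range(p):
                v = a[j] - delta
                if v > 0:
                    out[j] = np.sign(w[j]) * v / nt
            return out
    # unreachable bound (ties) or numerical trouble: sparsest feasible point
    kmax = 0
    for j in range(1, p):
        if a[j] > a[kmax]:
            kmax = j
    out[kmax] = np.sign(w[kmax])
    return out


def _l1_unit_project(w: np.ndarray, c: float) -> np.ndarray:
    if _HAVE_NUMBA:
        return _l1_project_kernel(np.ascontiguousarray(np.asarray(w, dtype=float)),
                                  float(c))
    return _l1_unit_project_py(w, c)


def _l1_unit_project_py(w: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold and L2-normalise w so that ||out||_2 = 1, ||out||_1 <= c.

    The threshold solves ||S(w,d)||_1 / ||S(w,d)||_2 = c exactly: within a
    segment of the sorted magnitudes the active support is fixed and the
    condition is a quadratic in d (delta = 0 when the plain normalised
    vector already satisfies the bound).  A zero input maps to zero.  When
    exact magnitude ties make the bound unreachable by thresholding (e.g. an
    all-equal vector with c = 1), the first maximal coordinate is kept alone
    — the sparsest feasible point.
    """
    w = np.asarray(w, dtype=float)
    peak = np.abs(w).max() if w.size else 0.0
    if peak == 0:
        return np.zeros_like(w)
    w = w / peak   # guard against under/overflow in the squared magnitudes
    norm = np.linalg.norm(w)
    out = w / norm
    if np.abs(out).sum() <= c:
        return out

    a = np.abs(w)
    s = np.sort(a)[::-1]
    S = np.cumsum(s)                 # S[k-1] = sum of top-k magnitudes
    Q = np.cumsum(s * s)
    # evaluate the L1/L2 ratio at each segment's lower edge (delta = next
    # magnitude down, or 0 for the last segment); support size there is k
    k = np.arange(1, len(s) + 1)
    b = np.append(s[1:], 0.0)
    num = S - k * b
    den2 = Q - 2 * b * S + k * b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den2 > 0, num / np.sqrt(np.maximum(den2, 0)), np.inf)
    # the ratio grows as delta moves down through the segments; the root
    # sits in the first segment whose lower-edge ratio reaches c
    idx = np.nonzero(ratio >= c)[0]
    delta = None
    if idx.size:
        j = int(idx[0])
        kk, Sk, Qk = j + 1, S[j], Q[j]
        A = kk * (kk - c * c)
        B = 2.0 * Sk * (c * c - kk)
        C = Sk * Sk - c * c * Qk
        if A != 0:
            disc = B * B - 4 * A * C
            if disc >= 0:
                r = np.sqrt(disc)
                lo_b, hi_b = b[j], s[j]
                for cand in ((-B + r) / (2 * A), (-B - r) / (2 * A)):
                    if lo_b - 1e-12 <= cand <= hi_b + 1e-12:
                        delta = float(min(max(cand, lo_b), hi_b))
                        break
    if delta is not None:
        t = soft_threshold(w, delta)
        nt = np.linalg.norm(t)
        if nt > 0 and np.abs(t).sum() / nt <= c + 1e-6:
            return t / nt
    # unreachable bound (ties) or numerical trouble: sparsest feasible point
    kmax = int(np.argmax(a))
    t = np.zeros_like(w)
    t[kmax] = np.sign(w[kmax])
    return t


def _check_centered(A: np.ndarray, name: str) -> None:
    if A.shape[0] > 1:
        scale = max(1.0, float(np.abs(A).max()))
        if np.abs(A.mean(axis=0)).max() > 1e-6 * scale:
            raise SCCAError(f"{name} must be column-centered")


def l1_scca_fit(X: np.ndarray, Y: AttributeMatrix | np.ndarray,
                params: SCCAParams, c_u: float | None = None) -> list:
    """Fit K sparse canonical pairs of (X, Y) by penalised matrix decomposition.

    Alternates u <- P(M v), v <- P(M' u) where P soft-thresholds to the L1
    bound and renormalises, with M = X'Y; initialisation is the leading
    singular-vector pair of the current (deflated) M, so the fit is fully
    deterministic.  After convergence M is deflated by d u v' with
    d = u' M v.  Returns fewer than K components (with a warning) once the
    deflated matrix is numerically zero.
    """
    params.validate()
    c_u = float(params.c_u_grid[0] if c_u is None else c_u)
    if c_u < 1.0:
        raise SCCAError("c_u must be >= 1")
    Ymat = Y.data if isinstance(Y, AttributeMatrix) else np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != Ymat.shape[0]:
        raise SCCAError("X and Y subject counts differ")
    _check_centered(X, "X")
    _check_centered(Ymat, "Y")

    M = X.T @ Ymat
    n_comp = params.n_components if params.n_components is not None else Ymat.shape[1]
    components: list[SCCAComponent] = []
    for _ in range(n_comp):
        if np.linalg.norm(M) < 1e-10:
            if len(components) < n_comp:
                warnings.warn(
                    f"cross-product matrix exhausted after {len(components)} "
                    f"components (requested {n_comp})",
                    stacklevel=2,
                )
            break
        # deterministic init: leading singular pair of the small E x k matrix
        U0, s0, V0t = np.linalg.svd(M, full_matrices=False)
        u = _l1_unit_project(U0[:, 0], c_u)
        v = _l1_unit_project(V0t[0], params.c_v)
        obj = float(u @ M @ v)
        for _ in range(params.max_iter):
            u = _l1_unit_project(M @ v, c_u)
            v = _l1_unit_project(M.T @ u, params.c_v)
            new_obj = float(u @ M @ v)
            if abs(new_obj - obj) < params.tol * max(1.0, abs(obj)):
                obj = new_obj
                break
            obj = new_obj
        # sign convention: dominant attribute weight positive
        k = int(np.argmax(np.abs(v))) if np.any(v) else 0
        if v[k] < 0:
            u, v = -u, -v
        d = float(u @ M @ v)
        xu, yv = X @ u, Ymat @ v
        if xu.std() > 0 and yv.std() > 0:
            corr = float(np.corrcoef(xu, yv)[0, 1])
        else:
            corr = 0.0
        components.append(SCCAComponent(u=u, v=v, value=d, correlation=corr))
        M = M - d * np.outer(u, v)
    return components


def diagnosis_only_components(components: list, roles: list,
                              tol: float = 1e-10) -> list:
    """Indices of components whose v loads on diagnosis and on no nuisance column."""
    diag = [k for k, r in enumerate(roles) if r == "diagnosis"]
    nuis = [k for k, r in enumerate(roles) if r == "nuisance"]
    keep = []
    for idx, comp in enumerate(components):
        v = np.abs(comp.v)
        if diag and np.any(v[diag] > tol) and (not nuis or np.all(v[nuis] <= tol)):
            keep.append(idx)
    return keep


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per subject, classes dealt round-robin after a seeded shuffle."""
    fold = np.empty(len(y), dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def select_features(X: np.ndarray, y: np.ndarray, age: np.ndarray, sex: np.ndarray,
                    params: SCCAParams, seed: int | None = None) -> np.ndarray:
    """Candidate FC set: union of diagnosis-only supports over folds × c_u grid.

    For each of ``params.n_folds`` stratified inner folds, L1-SCCA is fitted on
    the fold's training portion (feature standardisation computed on that
    portion only, so edge variance differences do not drive selection) at
    every value of the c_u grid, and the FC supports of the diagnosis-only
    components are pooled.  An empty union triggers a warning and a fallback
    fit at the least-sparse grid point on the full data.

    Returns sorted canonical edge ids.
    """
    params.validate()
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fold = _stratified_folds(y, params.n_folds, rng)
    for f in range(params.n_folds):
        tr = fold != f
        if len(np.unique(y[tr])) < 2 or min(np.bincount(y[tr])) < 2:
            raise SCCAError(f"inner fold {f}: fewer than 2 subjects per class")

    def _standardized(A: np.ndarray) -> np.ndarray:
        mu, sd = A.mean(axis=0), A.std(axis=0)
        return (A - mu) / np.where(sd > 0, sd, 1.0)

    selected: set[int] = set()
    for f in range(params.n_folds):
        tr = fold != f
        Xc = _standardized(X[tr])
        attrs = build_attributes(y[tr], np.asarray(age)[tr], np.asarray(sex)[tr])
        for c_u in params.c_u_grid:
            comps = l1_scca_fit(Xc, attrs, params, c_u=c_u)
            for k in diagnosis_only_components(comps, attrs.roles, params.nonzero_tol):
                selected.update(comps[k].support(params.nonzero_tol).tolist())
    if not selected:
        warnings.warn(
            "L1-SCCA selected no diagnosis-only FCs; falling back to the "
            "least-sparse grid point on the full data",
            stacklevel=2,
        )
        Xc = _standardized(X)
        attrs = build_attributes(y, age, sex)
        comps = l1_scca_fit(Xc, attrs, params, c_u=max(params.c_u_grid))
        for k in diagnosis_only_components(comps, attrs.roles, params.nonzero_tol):
            selected.update(comps[k].support(params.nonzero_tol).tolist())
    return np.array(sorted(selected), dtype=int)
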