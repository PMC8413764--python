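"""Sliding-window dynamic functional connectivity.

Each subject's T x C component matrix is carved into overlapping windows
weighted by a taper (a rectangle convolved with a Gaussian). Within each
window the covariance is estimated from an L1-regularized precision matrix
(graphical LASSO), converted to correlation, Fisher r-to-z transformed, and
optionally residualized across subjects against age and sex.

Window convention
-----------------
With T timepoints, window width W and step 1, the pipeline emits
``floor((T - W) / step)`` windows — e.g. 140 windows from 170 timepoints at
W = 30 — matching the margin that the Gaussian-extended taper requires at
the end of the scan. The inclusive ``T - W + 1`` convention is available
via ``enumerate_windows(..., inclusive=True)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso

try:  # the core solver skips per-call estimator/validation overhead, which
    # matters at tens of thousands of 5x5 problems per cohort; parameter
    # validation must be disabled as the public entry point does for its
    # nested calls
    from sklearn import config_context as _sk_config
    from sklearn.covariance._graph_lasso import _graphical_lasso as _glasso_core
except ImportError:  # pragma: no cover - fallback for other sklearn layouts
    _glasso_core = None


@dataclass
class TaperKernel:
    """Tapered window weights: rectangle convolved with a Gaussian."""

    width_tr: int
    sigma_tr: float
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.size != self.width_tr:
            raise ValueError("weights length must equal width_tr")
        if (w <= 0).any():
            raise ValueError("taper weights must be strictly positive")
        self.weights = w


@dataclass
class WindowedFCSeries:
    """Per-subject sequence of windowed Fisher-z connectivity matrices."""

    subject_id: str
    window_starts: np.ndarray  # 0-based, half-open [s, s+W)
    z_matrices: np.ndarray  # n_windows x C x C, symmetric, zero diagonal
    lasso_penalty: float
    residualized: bool = False

    @property
    def z_vectors(self) -> np.ndarray:
        """Off-diagonal upper-triangle vectors, n_windows x C(C-1)/2."""
        C = self.z_matrices.shape[1]
        iu = np.triu_indices(C, k=1)
        return self.z_matrices[:, iu[0], iu[1]]


def build_taper(width: int, sigma: float) -> TaperKernel:
    """Convolve a width-W rectangle with a Gaussian of given sigma (TRs).

    The Gaussian support is truncated at +/- 4 sigma; the convolution is
    cut back to the central W samples and normalized to peak 1. A zero
    sigma returns the plain rectangle.
    """
    if width < 2:
        raise ValueError("window width must be at least 2")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rect = np.ones(width)
    if sigma == 0:
        return TaperKernel(width, sigma, rect)
    half = int(np.ceil(4 * sigma))
    offsets = np.arange(-half, half + 1)
    gauss = np.exp(-0.5 * (offsets / sigma) ** 2)
    gauss /= gauss.sum()
    full = np.convolve(rect, gauss, mode="full")  # length width + 2*half
    start = (full.size - width) // 2
    weights = full[start : start + width]
    weights = weights / weights.max()
    return TaperKernel(width, sigma, weights)


def enumerate_windows(T: int, width: int, step: int = 1, inclusive: bool = False) -> np.ndarray:
    """Start indices of sliding windows over T timepoints.

    Default count is ``floor((T - width) / step)``; with ``inclusive=True``
    the final flush window is kept, giving ``floor((T - width) / step) + 1``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if T <= width:
        raise ValueError(f"scan ({T} volumes) shorter than window ({width})")
    n = (T - width) // step + (1 if inclusive else 0)
    n = max(n, 1)
    return np.arange(n) * step


def _weighted_corr(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Taper-weighted sample correlation of the rows of a W x C block."""
    wn = w / w.sum()
    mu = wn @ X
    Xc = X - mu
    cov = (Xc * wn[:, None]).T @ Xc
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def windowed_connectivity(
    data: np.ndarray,
    taper: TaperKernel,
    starts,
    lasso_penalty: float = 0.1,
    max_iter: int = 200,
) -> np.ndarray:
    """Sequence of regularized windowed correlation matrices.

    For each window the taper-weighted sample covariance is standardized to
    a correlation matrix, a sparse precision matrix is estimated by the
    graphical LASSO at the given penalty, and its inverse is converted back
    to correlation. As the penalty goes to zero the result converges to the
    taper-weighted sample correlation.
    """
    if lasso_penalty < 0:
        raise ValueError("lasso penalty must be nonnegative")
    X = np.asarray(data, dtype=float)
    W = taper.width_tr
    C = X.shape[1]
    out = np.empty((len(starts), C, C))
    for i, s in enumerate(starts):
        R = _weighted_corr(X[s : s + W], taper.weights)
        eigmin = np.linalg.eigvalsh(R).min()
        if eigmin < 1e-10:
            warnings.warn(f"window {i}: near-singular covariance; adding ridge jitter")
            R = R + np.eye(C) * (1e-8 * np.trace(R) / C)
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        cov = None
        # at vanishing penalty the solver must run to a much tighter
        # tolerance to actually reach the sample correlation; at working
        # penalties the library defaults are both stable and sufficient
        if lasso_penalty < 1e-3:
            tol, enet_tol = 1e-7, 1e-10
        else:
            tol, enet_tol = 1e-4, 1e-4
        # the coordinate-descent solver occasionally reports a non-SPD
        # failure on strongly correlated windows; fall back to the LARS
        # solver, then to escalating ridge jitter
        attempts = [("cd", 0.0), ("lars", 0.0), ("cd", 1e-4), ("lars", 1e-4),
                    ("cd", 5e-2), ("lars", 5e-2), ("cd", 0.2)]
        for mode, jitter in attempts:
            Rj = R if jitter == 0 else (R + np.eye(C) * jitter) / (1 + jitter)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if _glasso_core is not None:
                        with _sk_config(skip_parameter_validation=True):
                            cov = _glasso_core(
                                Rj,
                                max(lasso_penalty, 1e-12),
                                mode=mode,
                                max_iter=max_iter,
                                tol=tol,
                                enet_tol=enet_tol,
                            )[0]
                    else:
                        cov, _ = graphical_lasso(
                            Rj,
                            alpha=max(lasso_penalty, 1e-12),
                            mode=mode,
                            max_iter=max_iter,
                            tol=tol,
                            enet_tol=enet_tol,
                        )
                break
            except FloatingPointError:
                continue
        if cov is None:
            raise RuntimeError(f"graphical LASSO failed to converge in window {i}")
        d = np.sqrt(np.diag(cov))
        out[i] = cov / np.outer(d, d)
    return out


def select_lasso_penalty(
    data: np.ndarray,
    taper: TaperKernel,
    starts,
    grid: np.ndarray | None = None,
) -> float:
    """Pick a subject-level L1 penalty over a logarithmic grid.

    Scores each candidate penalty by the unregularized Gaussian
    log-likelihood of the windowed data under the regularized estimates,
    summed over windows, and returns the maximizer. The default grid has
    10 logarithmically spaced values in [0.01, 1].
    """
    if grid is None:
        grid = np.logspace(-2, 0, 10)
    X = np.asarray(data, dtype=float)
    W = taper.width_tr
    best, best_ll = None, -np.inf
    for lam in grid:
        ll = 0.0
        mats = windowed_connectivity(X, taper, starts, lam)
        for i, s in enumerate(starts):
            R_emp = _weighted_corr(X[s : s + W], taper.weights)
            prec = np.linalg.inv(mats[i])
            sign, logdet = np.linalg.slogdet(prec)
            ll += sign * logdet - np.trace(R_emp @ prec)
        if ll > best_ll:
            best, best_ll = lam, ll
    return float(best)


def fisher_z_transform(r):
    """Variance-stabilizing transform z = arctanh(r), clipped near |r| = 1."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) > 1 + 1e-12).any():
        raise ValueError("correlations must satisfy |r| <= 1")
    return np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))


def subject_windowed_fc(
    data: np.ndarray,
    subject_id: str = "",
    width: int = 30,
    sigma: float = 3.0,
    step: int = 1,
    lasso_penalty: float = 0.1,
) -> WindowedFCSeries:
    """Full per-subject windowed pipeline: taper, glasso, Fisher z."""
    taper = build_taper(width, sigma)
    starts = enumerate_windows(data.shape[0], width, step)
    corrs = windowed_connectivity(data, taper, starts, lasso_penalty)
    z = fisher_z_transform(corrs)
    for m in z:
        np.fill_diagonal(m, 0.0)
    return WindowedFCSeries(
        subject_id=subject_id,
        window_starts=starts,
        z_matrices=z,
        lasso_penalty=lasso_penalty,
    )


def residualize_connectivity(z_stack: np.ndarray, age, sex) -> np.ndarray:
    """Residualize windowed z values against age and sex across subjects.

    ``z_stack`` is an n_subjects x n_windows x P array. For every
    (window, pair) cell an across-subject linear model on
    [intercept, age, sex] is fitted and the cell is replaced by its
    residual plus the fitted intercept, so confound-driven variance is
    removed while the overall level is preserved. Covariates are centered
    before fitting so that the intercept is the grand mean and the removed
    component is the covariate *deviation* effect; without centering every
    subject would be shifted by a large shared multiple of the slope
    pattern, which distorts correlation-distance geometry downstream.
    Constant covariates are dropped with a warning.
    """
    Z = np.asarray(z_stack, dtype=float)
    n = Z.shape[0]
    cols, names = [np.ones(n)], ["intercept"]
    for name, v in (("age", age), ("sex", sex)):
        v = np.asarray(v, dtype=float)
        if v.size != n:
            raise ValueError(f"{name} must have one value per subject")
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {name} is constant; dropped")
            continue
        cols.append(v - v.mean())
        names.append(name)
    X = np.column_stack(cols)
    if n < X.shape[1] + 3:
        raise ValueError("need at least 3 more subjects than covariates")
    flat = Z.reshape(n, -1)
    beta = np.linalg.lstsq(X, flat, rcond=None)[0]
    resid = flat - X @ beta
    out = resid + beta[0]  # keep the grand intercept
    return out.reshape(Z.shape)
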