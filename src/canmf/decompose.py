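"""Trace normalization and the four decomposition methods.

All methods consume a time x neurons trace matrix normalized to [0, 1] by a
single *global* min/max (per-neuron scaling would erase the relative
amplitude differences between traces, which carry information about how
strongly each neuron is driven).

The central method is non-negative matrix factorization, X ~ W H with
W, H >= 0: each row of H is read as a sub-network (a neuron-weight vector)
and the matching column of W as that sub-network's activity over time. The
number of sub-networks k is selected by an adapted Akaike information
criterion, AIC = 2 * (fit / sigma^2 + k * (n + t)), scanned over k and
minimized. PCA, ICA and UMAP are fitted under matching conventions as
baselines; not every method yields every attribute (UMAP has no activity
time series and no variance explained, ICA no variance explained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.decomposition import NMF, FastICA
from sklearn.exceptions import ConvergenceWarning

from .simulate import TraceMatrix

__all__ = [
    "Decomposition",
    "RankScanResult",
    "normalize_global",
    "variance_explained",
    "nmf_aic",
    "fit_nmf",
    "scan_rank",
    "select_rank",
    "fit_pca",
    "fit_ica",
    "fit_umap",
]

NMF_TOL = 1e-4
NMF_MAX_ITER = 1000
ICA_MAX_ITER = 500
ICA_TOL = 1e-4


@dataclass
class Decomposition:
    """A fitted decomposition under a shared shape contract.

    ``weights`` (H) is always k x n_neurons; ``activities`` (W) is
    n_steps x k when the method produces one (all but UMAP). Fields that a
    method does not define are ``None``.
    """

    method: str
    k: int
    weights: np.ndarray
    activities: np.ndarray | None = None
    r_squared: float | None = None
    aic: float | None = None
    variance_explained_per_component: np.ndarray | None = None
    converged: bool = True
    n_iter: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[1]


@dataclass
class RankScanResult:
    """Trajectory of an NMF rank scan and the selected component count."""

    k_values: list[int]
    aic_values: list[float]
    r2_values: list[float]
    selected_k: int
    exhausted: bool = False  # AIC still decreasing at k_max


def _as_array(X) -> np.ndarray:
    if isinstance(X, TraceMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def normalize_global(X) -> np.ndarray:
    """Rescale a trace matrix to [0, 1] by its global minimum and maximum.

    One (min, max) pair for the whole matrix — not per neuron — so the
    relative dynamic range between neurons is preserved.
    """
    values = _as_array(X)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant trace matrix (zero range)")
    return (values - lo) / (hi - lo)


def variance_explained(X, W: np.ndarray, H: np.ndarray) -> float:
    """Coefficient of determination R^2 of the reconstruction W @ H.

    R^2 = 1 - SS_res / SS_tot with SS_res the summed squared reconstruction
    error and SS_tot the summed squared deviation from the grand mean of X.
    """
    values = _as_array(X)
    ss_tot = float(((values - values.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("SS_tot is zero: R^2 undefined for a constant matrix")
    ss_res = float(((values - W @ H) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def nmf_aic(X, W: np.ndarray, H: np.ndarray, k: int, literal_r2: bool = False) -> float:
    """Adapted AIC for an NMF model: ``2 * (fit / sigma^2 + k * (n + t))``.

    ``sigma^2`` is the grand sample variance of the data matrix. The fit
    term is the summed squared reconstruction error SS_res, so the score
    falls while added components remove real structure and rises once the
    per-component penalty ``2*(n+t)`` outweighs the residual reduction.
    ``literal_r2=True`` instead places R^2 itself in the numerator.
    """
    values = _as_array(X)
    sigma2 = float(values.var())
    if sigma2 == 0.0:
        raise ValueError("data variance is zero: AIC undefined")
    n = values.shape[1]
    t = values.shape[0]
    if literal_r2:
        fit = variance_explained(values, W, H)
    else:
        fit = float(((values - W @ H) ** 2).sum())
    return 2.0 * (fit / sigma2 + k * (n + t))


def _order_by_activity_variance(W: np.ndarray, H: np.ndarray):
    order = np.argsort(-W.var(axis=0), kind="stable")
    return W[:, order], H[order]


def fit_nmf(X, k: int, literal_aic: bool = False) -> Decomposition:
    """Fit NMF at rank k from a deterministic nndsvd start.

    Frobenius-loss coordinate descent (tol 1e-4, at most 1000 iterations)
    started from plain nndsvd, which is SVD-derived and keeps the fit fully
    deterministic: two runs on the same matrix give identical factors.
    Components are reported in order of decreasing activity variance.
    """
    values = _as_array(X)
    n = values.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of neurons n={n}")
    if np.any(values < 0):
        raise ValueError("NMF requires a non-negative input matrix")
    model = NMF(
        n_components=k,
        init="nndsvd",
        solver="cd",
        beta_loss="frobenius",
        tol=NMF_TOL,
        max_iter=NMF_MAX_ITER,
        random_state=0,  # nndsvd is deterministic; this pins solver internals too
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(values)
    H = model.components_
    W, H = _order_by_activity_variance(W, H)
    return Decomposition(
        method="nmf",
        k=k,
        weights=H,
        activities=W,
        r_squared=variance_explained(values, W, H),
        aic=nmf_aic(values, W, H, k, literal_r2=literal_aic),
        converged=model.n_iter_ < NMF_MAX_ITER,
        n_iter=model.n_iter_,
    )


def select_rank(aic_values: list[float]) -> tuple[int, bool]:
    """First-increase rule on an AIC trajectory starting at k=1.

    Returns ``(selected_k, exhausted)``: the k preceding the first AIC
    increase, or the last k scanned (``exhausted=True``) when the
    trajectory is still decreasing at the end of the scan.
    """
    for i in range(1, len(aic_values)):
        if aic_values[i - 1] < aic_values[i]:
            return i, False  # k = i (1-based: the previous entry)
    return len(aic_values), True


def scan_rank(
    X,
    k_max: int | None = None,
    exhaustive: bool = False,
    literal_aic: bool = False,
) -> RankScanResult:
    """Scan NMF ranks k = 1, 2, ... and select one by the adapted AIC.

    By default fitting stops at the first AIC increase and the preceding k
    is selected. ``exhaustive=True`` fits every k up to ``k_max`` and
    selects the global AIC minimizer. ``k_max`` defaults to
    ``min(n_neurons, 30)``.
    """
    values = _as_array(X)
    n = values.shape[1]
    if k_max is None:
        k_max = min(n, 30)
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of neurons n={n}")
    k_values: list[int] = []
    aics: list[float] = []
    r2s: list[float] = []
    for k in range(1, k_max + 1):
        fit = fit_nmf(values, k, literal_aic=literal_aic)
        k_values.append(k)
        aics.append(fit.aic)
        r2s.append(fit.r_squared)
        if not exhaustive and len(aics) >= 2 and aics[-2] < aics[-1]:
            break
    if exhaustive:
        selected = k_values[int(np.argmin(aics))]
        exhausted = selected == k_max
    else:
        selected, exhausted = select_rank(aics)
    return RankScanResult(k_values, aics, r2s, selected, exhausted)


def fit_pca(X, k: int) -> Decomposition:
    """PCA of the column-centered trace matrix via the SVD.

    Each neuron's trace is mean-centered (no variance scaling), then
    ``Xc = U S Vt``; the rows of H are the top-k right singular vectors and
    W = U_k S_k their projections. ``variance_explained_per_component``
    holds the squared-singular-value proportions (the variance each
    component accounts for); the linear singular-value proportions are kept
    in ``extras["singular_value_proportion"]``. ``r_squared`` is the R^2 of
    the rank-k reconstruction of the centered matrix, which equals the
    cumulative variance proportion.
    """
    values = _as_array(X)
    t, n = values.shape
    if k < 1 or k > min(t, n):
        raise ValueError(f"k={k} must lie in [1, min(n_steps, n_neurons)={min(t, n)}]")
    centered = values - values.mean(axis=0)
    U, s, Vt = sla.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    W = U[:, :k] * s[:k]
    H = Vt[:k]
    return Decomposition(
        method="pca",
        k=k,
        weights=H,
        activities=W,
        r_squared=variance_explained(centered, W, H),
        variance_explained_per_component=s[:k] ** 2 / (s**2).sum(),
        extras={"singular_value_proportion": s[:k] / s.sum(), "singular_values": s[:k]},
    )


def fit_ica(X, k: int, seed: int = 0) -> Decomposition:
    """FastICA on the column-centered trace matrix.

    Traces are mean-centered but *not* individually variance-scaled, so the
    relative activity magnitudes between neurons survive the whitening
    step. Parallel (symmetric) estimation with the logcosh contrast;
    ``weights`` holds the rows of the unmixing matrix and ``activities``
    the estimated sources. Non-convergence within the iteration cap is
    flagged on the result rather than raised. No variance explained is
    defined for ICA.
    """
    values = _as_array(X)
    t, n = values.shape
    if k < 1 or k > min(t, n):
        raise ValueError(f"k={k} must lie in [1, min(n_steps, n_neurons)={min(t, n)}]")
    centered = values - values.mean(axis=0)
    model = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=ICA_MAX_ITER,
        tol=ICA_TOL,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        S = model.fit_transform(centered)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    W, H = _order_by_activity_variance(S, model.components_)
    return Decomposition(
        method="ica",
        k=k,
        weights=H,
        activities=W,
        converged=converged,
        n_iter=getattr(model, "n_iter_", None),
        seed=seed,
    )


def fit_umap(
    X,
    k: int,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
) -> Decomposition:
    """UMAP embedding of the *neurons* into k dimensions.

    The trace matrix is transposed so each neuron is one point described by
    its time series, and the neurons are embedded into k dimensions. The
    embedding (k x n_neurons) plays the role of the weight matrix H; UMAP
    produces no activity time series and no variance explained. A fixed
    seed makes the embedding deterministic (at the cost of single-threaded
    layout optimization).
    """
    import umap  # deferred: slow import, numba compilation on first use

    values = _as_array(X)
    n = values.shape[1]
    if k < 1 or k >= n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_neurons={n}")
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_neurons={n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = umap.UMAP(
            n_components=k,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=seed,
        )
        embedding = model.fit_transform(values.T)
    return Decomposition(
        method="umap",
        k=k,
        weights=embedding.T,
        seed=seed,
        extras={"n_neighbors": n_neighbors, "min_dist": min_dist, "metric": metric},
    )
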