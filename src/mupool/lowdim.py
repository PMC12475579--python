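"""Linear low-dimensional analysis of smoothed discharge-rate matrices.

Covers factorability (Kaiser-Meyer-Olkin sampling adequacy), dimensionality
selection by parallel analysis against column-shuffled surrogates,
unrotated component extraction (PCA by eigendecomposition of the
correlation matrix; factor analysis by principal-axis factoring), and the
cross-correlation statistics used to relate component time courses to
force and to each other across repeated trials.

All operations accept either a :class:`~mupool.preprocess.SmoothedRateMatrix`
(standardized) or a plain (r, c) array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .preprocess import SmoothedRateMatrix, decimate_columns

__all__ = [
    "FactorabilityReport",
    "ParallelAnalysisResult",
    "ComponentSet",
    "CorrelationResult",
    "kmo",
    "parallel_analysis",
    "extract_components",
    "xcorr_peak",
    "component_force_correlation",
    "trial_consistency",
]

KMO_FACTORABLE = 0.70


def _as_array(matrix: SmoothedRateMatrix | np.ndarray) -> tuple[np.ndarray, float | None]:
    if isinstance(matrix, SmoothedRateMatrix):
        return matrix.data, matrix.fs
    return np.asarray(matrix, dtype=float), None


@dataclass
class FactorabilityReport:
    kmo_overall: float
    kmo_per_unit: np.ndarray
    factorable: bool


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray  # descending
    null_upper: np.ndarray            # per-rank upper CI bound of surrogates
    n_retain: int
    n_reps: int
    alpha: float
    seed: int | None


@dataclass
class ComponentSet:
    method: str                       # "PCA" | "FA"
    loadings: np.ndarray              # (units, components)
    scores: np.ndarray                # (time, components)
    variance_explained_pct: np.ndarray
    unit_ids: list[str] | None = None
    fs: float | None = None
    communalities: np.ndarray | None = None  # FA only
    sign_fixed: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class CorrelationResult:
    peak_r: float                     # signed r at the lag maximizing |r|
    lag_s: float
    window_scheme: str = "whole"


# ---------------------------------------------------------------------------
# Factorability
# ---------------------------------------------------------------------------

def kmo(matrix: SmoothedRateMatrix | np.ndarray) -> FactorabilityReport:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = Σr² / (Σr² + Σp²) over off-diagonal entries, where p are the
    anti-image partial correlations obtained from the inverse correlation
    matrix.  Values above 0.70 indicate a matrix appropriate for
    factorization.
    """
    X, _ = _as_array(matrix)
    if X.shape[1] < 2:
        raise ValueError("KMO needs at least 2 units")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular (perfectly collinear units); "
            "consider removing duplicated units"
        ) from exc
    d = np.sqrt(np.abs(np.diag(Rinv)))
    P = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = R[off] ** 2
    p2 = P[off] ** 2
    overall = float(r2.sum() / (r2.sum() + p2.sum()))
    per_unit = np.array(
        [
            (R[j, off[j]] ** 2).sum()
            / ((R[j, off[j]] ** 2).sum() + (P[j, off[j]] ** 2).sum())
            for j in range(R.shape[0])
        ]
    )
    return FactorabilityReport(overall, per_unit, overall > KMO_FACTORABLE)


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------

def parallel_analysis(
    matrix: SmoothedRateMatrix | np.ndarray,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    decimate_to_hz: float | None = None,
    joint_shuffle: bool = False,
) -> ParallelAnalysisResult:
    """Retain components whose eigenvalues beat shuffled surrogates.

    Surrogates permute each column's time samples independently (destroying
    cross-correlations, preserving marginals); the per-rank upper bound of
    the (1 − alpha) confidence interval over ``n_reps`` surrogate PCA
    eigenvalue sets defines the retention criterion.  ``joint_shuffle``
    permutes whole rows instead (preserving instantaneous cross-sections),
    offered for sensitivity analysis only.
    """
    X, fs = _as_array(matrix)
    r, c = X.shape
    if c < 2:
        raise ValueError("need at least 2 units")
    if r <= c:
        raise ValueError("need more time samples than units")
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} gives unstable CI bounds", stacklevel=2)
    if decimate_to_hz is not None and fs is not None and fs > decimate_to_hz:
        X, fs = decimate_columns(X, fs, decimate_to_hz)
        r = X.shape[0]
    rng = np.random.default_rng(seed)

    observed = _corr_eigenvalues(X)
    null = np.empty((n_reps, c))
    for k in range(n_reps):
        if joint_shuffle:
            Xs = X[rng.permutation(r)]
        else:
            Xs = rng.permuted(X, axis=0)
        null[k] = _corr_eigenvalues(Xs)
    upper = np.percentile(null, 100.0 * (1.0 - alpha / 2.0), axis=0)
    n_retain = int(np.sum(observed > upper))
    return ParallelAnalysisResult(
        observed_eigenvalues=observed,
        null_upper=upper,
        n_retain=n_retain,
        n_reps=n_reps,
        alpha=alpha,
        seed=seed if isinstance(seed, int) else None,
    )


def _corr_eigenvalues(X: np.ndarray) -> np.ndarray:
    R = np.corrcoef(X, rowvar=False)
    return np.linalg.eigvalsh(R)[::-1]


# ---------------------------------------------------------------------------
# Component extraction
# ---------------------------------------------------------------------------

def extract_components(
    matrix: SmoothedRateMatrix | np.ndarray,
    method: str = "PCA",
    n_components: int = 2,
    fa_extraction: str = "paf",
) -> ComponentSet:
    """Unrotated PCA or factor-analysis components of the rate matrix.

    PCA eigendecomposes the correlation matrix (columns are standardized,
    so covariance equals correlation); loadings are orthonormal
    eigenvectors and scores their time courses.  FA uses principal-axis
    factoring with squared-multiple-correlation initial communalities
    (``fa_extraction="ml"`` switches to maximum likelihood).  Each
    component's sign is fixed so that its peak-lag correlation with the
    mean smoothed rate across units is positive — defined even when force
    was not recorded.  ``variance_explained_pct`` follows the PCA
    convention (eigenvalue share); for FA it is the squared-loading share.
    """
    X, fs = _as_array(matrix)
    r, c = X.shape
    if n_components > c:
        raise ValueError(f"n_components={n_components} exceeds c={c} units")
    unit_ids = matrix.unit_ids if isinstance(matrix, SmoothedRateMatrix) else None
    if isinstance(matrix, SmoothedRateMatrix) and not matrix.standardized:
        warnings.warn("matrix is not standardized; PCA assumes z-scored columns",
                      stacklevel=2)
    try:
        report = kmo(X)
        if not report.factorable:
            warnings.warn(
                f"KMO={report.kmo_overall:.2f} <= {KMO_FACTORABLE}: matrix may "
                "not be appropriate for factorization", stacklevel=2,
            )
    except (ValueError, np.linalg.LinAlgError):
        warnings.warn("KMO unavailable (singular correlation matrix)", stacklevel=2)
    R = np.corrcoef(X, rowvar=False)
    Xc = X - X.mean(axis=0)

    method = method.upper()
    communalities = None
    if method == "PCA":
        eigvals, eigvecs = np.linalg.eigh(R)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        loadings = eigvecs[:, :n_components]
        scores = Xc @ loadings
        variance = 100.0 * np.clip(eigvals[:n_components], 0.0, None) / c
    elif method == "FA":
        if fa_extraction == "ml":
            from sklearn.decomposition import FactorAnalysis

            Z = Xc / X.std(axis=0, ddof=0)
            fa = FactorAnalysis(n_components=n_components, rotation=None)
            fa.fit(Z)
            loadings = fa.components_.T.copy()
            communalities = (loadings**2).sum(axis=1)
            scores = Xc @ np.linalg.solve(R, loadings)
        else:
            loadings, communalities = _fit_factors(R, n_components)
            # regression-method factor scores
            scores = Xc @ np.linalg.solve(R, loadings)
        variance = 100.0 * (loadings**2).sum(axis=0) / c
    else:
        raise ValueError("method must be 'PCA' or 'FA'")

    mean_rate = Xc.mean(axis=1)
    for k in range(n_components):
        # degenerate (zero-variance) scores have no meaningful sign
        if scores[:, k].std() < 1e-12 or mean_rate.std() < 1e-12:
            continue
        res = xcorr_peak(scores[:, k], mean_rate, fs=fs or 1.0)
        if res.peak_r < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    return ComponentSet(
        method=method,
        loadings=loadings,
        scores=scores,
        variance_explained_pct=variance,
        unit_ids=list(unit_ids) if unit_ids else None,
        fs=fs,
        communalities=communalities,
    )


def _fit_factors(
    R: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis factoring with SMC initial communalities."""
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    h = 1.0 - 1.0 / np.diag(Rinv)
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        eigvals, eigvecs = np.linalg.eigh(Rh)
        order = np.argsort(eigvals)[::-1][:k]
        lam = np.clip(eigvals[order], 0.0, None)
        L = eigvecs[:, order] * np.sqrt(lam)
        h_new = np.clip((L**2).sum(axis=1), 0.0, 1.0 - 1e-9)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    Rh = R.copy()
    np.fill_diagonal(Rh, h)
    eigvals, eigvecs = np.linalg.eigh(Rh)
    order = np.argsort(eigvals)[::-1][:k]
    lam = np.clip(eigvals[order], 0.0, None)
    L = eigvecs[:, order] * np.sqrt(lam)
    return L, h


# ---------------------------------------------------------------------------
# Cross-correlation statistics
# ---------------------------------------------------------------------------

def xcorr_peak(
    a: np.ndarray,
    b: np.ndarray,
    fs: float,
    max_lag_s: float = 2.0,
    zero_lag_only: bool = False,
) -> CorrelationResult:
    """Normalized cross-correlation peak between two detrended series.

    Both inputs are linearly detrended, then the biased normalized
    cross-correlation is scanned over lags in [−max_lag_s, +max_lag_s];
    the signed r at the lag maximizing |r| is returned.  Positive lag means
    ``b`` lags (is delayed relative to) ``a``.
    """
    a0 = np.asarray(a, dtype=float)
    b0 = np.asarray(b, dtype=float)
    if a0.shape != b0.shape:
        raise ValueError("series must have equal length")
    a = signal.detrend(a0, type="linear")
    b = signal.detrend(b0, type="linear")
    n = len(a)
    sa, sb = a.std(), b.std()
    # degenerate after detrend (constants and pure ramps included)
    if sa <= 1e-10 * max(1.0, np.abs(a0).max()) or \
            sb <= 1e-10 * max(1.0, np.abs(b0).max()):
        raise ValueError("zero-variance input")
    if zero_lag_only:
        r0 = float(np.dot(a, b) / (n * sa * sb))
        return CorrelationResult(r0, 0.0)
    max_lag = int(round(max_lag_s * fs))
    max_lag = min(max_lag, n - 1)
    # c[m] = sum_t b[t] a[t - (m - (n-1))]; lag = m - (n-1) > 0 <=> b delayed
    c = signal.correlate(b, a, mode="full", method="auto")
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_lag
    c, lags = c[keep], lags[keep]
    r = c / (n * sa * sb)
    # among equal |r|, prefer the smallest |lag|
    order = np.lexsort((np.abs(lags), -np.abs(r)))
    best = order[0]
    return CorrelationResult(float(r[best]), float(lags[best] / fs))


def component_force_correlation(
    components: ComponentSet,
    force: np.ndarray,
    fs: float,
    max_lag_s: float = 2.0,
    zero_lag_only: bool = False,
) -> list[CorrelationResult]:
    """Peak cross-correlation of each component score with the force signal.

    The force should already be low-pass filtered and cut to the analysis
    window; detrending happens inside the correlation.  Positive lag means
    force follows the neural component (electromechanical delay).
    """
    force = np.asarray(force, dtype=float)
    if force.size != components.scores.shape[0]:
        raise ValueError(
            "force length does not match component scores; if force was not "
            "recorded (e.g. a discharge-times-only deposit), this analysis "
            "is unavailable"
        )
    return [
        xcorr_peak(components.scores[:, k], force, fs, max_lag_s, zero_lag_only)
        for k in range(components.n_components)
    ]


def trial_consistency(
    components_by_trial: Sequence[ComponentSet],
    fs: float | None = None,
    window_s: float = 5.0,
    max_lag_s: float = 2.0,
) -> dict[tuple[int, int], np.ndarray]:
    """Across-trial consistency of component time courses.

    For every trial pair and component, the scores are split into
    non-overlapping ``window_s`` windows (trailing remainder discarded),
    the peak cross-correlation is computed per window, and the signed peaks
    are averaged.  Returns {(i, j): array of per-component means} with
    0-based trial positions i < j.
    """
    if len(components_by_trial) < 2:
        raise ValueError("need at least 2 trials")
    fs = fs or components_by_trial[0].fs
    if fs is None:
        raise ValueError("sampling rate unknown; pass fs explicitly")
    lengths = {cs.scores.shape[0] for cs in components_by_trial}
    if len(lengths) > 1:
        raise ValueError("scores must have equal length across trials")
    n = lengths.pop()
    w = int(round(window_s * fs))
    if w > n:
        raise ValueError("record shorter than one consistency window")
    n_windows = n // w
    k = components_by_trial[0].n_components
    out: dict[tuple[int, int], np.ndarray] = {}
    for i in range(len(components_by_trial)):
        for j in range(i + 1, len(components_by_trial)):
            means = np.empty(k)
            for comp in range(k):
                peaks = []
                for win in range(n_windows):
                    sl = slice(win * w, (win + 1) * w)
                    res = xcorr_peak(
                        components_by_trial[i].scores[sl, comp],
                        components_by_trial[j].scores[sl, comp],
                        fs,
                        max_lag_s,
                    )
                    peaks.append(res.peak_r)
                means[comp] = float(np.mean(peaks))
            out[(i, j)] = means
    return out
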