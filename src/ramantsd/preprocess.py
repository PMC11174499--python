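"""Spectral preprocessing chain for TSD modeling.

Order is fixed: truncate to the analysis window (default
315-1800 cm^-1), asymmetric Whittaker baseline correction
(lambda = 850, p = 0.001), total-area normalization, then mean
centering at the matrix level.  Outlier map spectra (saturated
fluorescence background) are rejected by a two-stage rule: a gross
RMS-deviation screen against the map mean, confirmed by Hotelling T^2
on PCA scores.

The baseline estimator is the asymmetric penalized-least-squares
(Whittaker) smoother: solve (W + lam * D'D) z = W y with D the d-th
order finite-difference operator, then reassign weights w_i = p where
y_i > z_i (points above the baseline are treated as peak, not
baseline) and (1 - p) elsewhere, iterating to a weight fixed point.
With p << 1 the baseline is pushed underneath the peaks; lam sets its
stiffness on the channel grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.linalg import splu

from .spectra import RamanSpectrum, SpectraDataset

__all__ = [
    "BaselineParams",
    "PreprocessReport",
    "truncate",
    "whittaker_baseline",
    "correct_baseline",
    "normalize_total_area",
    "mean_center",
    "detect_outliers",
    "preprocess_dataset",
]


@dataclass
class BaselineParams:
    """Asymmetric Whittaker smoother parameters.

    ``lam`` is taken on the channel spacing of the working grid (the
    default 1 cm^-1); densifying the grid requires rescaling it.
    """

    lam: float = 850.0
    p: float = 0.001
    diff_order: int = 2
    max_iter: int = 50
    tol: float = 0.0  # fraction of weights allowed to flip at convergence

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.diff_order < 1:
            raise ValueError("diff_order must be >= 1")


@dataclass
class PreprocessReport:
    n_input: int
    n_removed_outliers: int
    removed_ids: list
    window: tuple
    train_mean: np.ndarray | None = None
    baseline_params: BaselineParams = field(default_factory=BaselineParams)

    def __post_init__(self):
        if self.n_removed_outliers != len(self.removed_ids):
            raise ValueError("n_removed_outliers must equal |removed_ids|")


def truncate(spectrum: RamanSpectrum, low: float, high: float) -> RamanSpectrum:
    """Retain channels with ``low <= nu <= high`` (closed interval)."""
    if low >= high:
        raise ValueError("low must be < high")
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if mask.sum() < 2:
        raise ValueError(f"truncation window [{low}, {high}] leaves < 2 channels")
    return RamanSpectrum(
        spectrum.wavenumbers[mask], spectrum.intensities[mask], spectrum.meta.copy()
    )


_DTD_CACHE: dict = {}


def _penalty_matrix(n: int, diff_order: int) -> sparse.csc_matrix:
    key = (n, diff_order)
    if key not in _DTD_CACHE:
        # d-th order finite-difference operator as repeated first differences
        D = sparse.eye_array(n, format="csc")
        for k in range(diff_order):
            m = n - k
            Dk = sparse.diags_array([-np.ones(m - 1), np.ones(m - 1)], offsets=[0, 1],
                                    shape=(m - 1, m), format="csc")
            D = Dk @ D
        _DTD_CACHE[key] = (D.T @ D).tocsc()
    return _DTD_CACHE[key]


def whittaker_baseline(
    intensity, params: BaselineParams | None = None, weights=None
) -> np.ndarray:
    """Estimate a baseline by iterative asymmetric penalized least squares.

    Parameters
    ----------
    intensity : 1-D array
    params : BaselineParams
    weights : optional 1-D array
        If given, the weights are held fixed and a single penalized
        solve is returned (used by tests to freeze the linear map).
    """
    params = params or BaselineParams()
    y = np.asarray(intensity, float)
    if y.ndim != 1:
        raise ValueError("intensity must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensity values")
    n = y.size
    if n < 2 * params.diff_order + 1:
        raise ValueError("input shorter than 2*diff_order + 1")
    DTD = _penalty_matrix(n, params.diff_order)

    def solve(w):
        A = sparse.diags_array([w], offsets=[0], shape=(n, n), format="csc") + params.lam * DTD
        return splu(A.tocsc()).solve(w * y)

    if weights is not None:
        return solve(np.asarray(weights, float))

    w = np.ones(n)
    z = solve(w)
    for _ in range(params.max_iter):
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        flipped = np.mean(w_new != w) if w is not None else 1.0
        w = w_new
        z = solve(w)
        if flipped <= params.tol:
            return z
    warnings.warn(
        "asymmetric Whittaker baseline did not reach a weight fixed point; "
        "returning last iterate",
        RuntimeWarning,
    )
    return z


def correct_baseline(
    spectrum: RamanSpectrum, params: BaselineParams | None = None
) -> RamanSpectrum:
    """Subtract the asymmetric Whittaker baseline (negatives permitted)."""
    z = whittaker_baseline(spectrum.intensities, params)
    return spectrum.with_intensities(spectrum.intensities - z)


def normalize_total_area(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Divide by the trapezoidal area so the spectrum integrates to 1."""
    area = spectrum.area()
    if area <= 0:
        raise ValueError(
            f"nonpositive total area ({area:g}); baseline correction likely failed"
        )
    return spectrum.with_intensities(spectrum.intensities / area)


def mean_center(matrix, train_mean=None):
    """Column-center a spectra-by-channels matrix.

    With ``train_mean`` given, that mean is subtracted instead
    (test-set contract).  Returns ``(centered, mean)``.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("matrix must be 2-D with >= 1 row")
    if train_mean is None:
        mu = X.mean(axis=0)
    else:
        mu = np.asarray(train_mean, float)
        if mu.shape != (X.shape[1],):
            raise ValueError(
                f"mean length {mu.shape} does not match channel count {X.shape[1]}"
            )
    return X - mu, mu


def _hotelling_t2_insample_limit(n: int, a: int, level: float) -> float:
    """Exact per-point T^2 limit for scores of the fitting sample.

    For a point included in the PCA fit, T^2 * n / (n-1)^2 follows a
    Beta(a/2, (n-a-1)/2) distribution, which (unlike the F-form limit
    for future samples) stays below the algebraic maximum (n-1)^2/n.
    """
    q = stats.beta.ppf(level, a / 2.0, (n - a - 1) / 2.0)
    return (n - 1) ** 2 / n * q


def detect_outliers(
    map_spectra,
    k: float = 3.0,
    n_components: int = 4,
    t2_level: float = 0.99,
):
    """Two-stage saturated-spectrum rejection within one acquisition map.

    Stage 1 flags spectra whose RMS deviation from the map-mean spectrum
    exceeds ``k`` times the median RMS deviation; stage 2 confirms with
    Hotelling T^2 on PCA scores (up to ``n_components`` PCs) above the
    in-sample ``t2_level`` limit.  Only spectra flagged by both stages
    are removed.  Returns ``(kept, removed)`` lists.

    """
    spectra = list(map_spectra)
    n = len(spectra)
    if n < 3:
        raise ValueError("need at least 3 spectra per map")
    X = np.vstack([s.intensities for s in spectra])

    mean_spec = X.mean(axis=0)
    rms = np.sqrt(np.mean((X - mean_spec) ** 2, axis=1))
    med = np.median(rms)
    stage1 = rms > k * med if med > 0 else rms > 0

    Xc = X - mean_spec
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)
    keep = lam > max(lam[0], 1e-300) * 1e-10
    a = int(min(n_components, keep.sum(), n - 2))
    if a < 1:
        stage2 = np.zeros(n, dtype=bool)  # degenerate: all spectra identical
    else:
        scores = U[:, :a] * s[:a]
        t2 = np.sum(scores**2 / lam[:a], axis=1)
        stage2 = t2 > _hotelling_t2_insample_limit(n, a, t2_level)

    flagged = stage1 & stage2
    if flagged.all():
        raise ValueError("every spectrum in the map was flagged; degenerate map")
    kept, removed = [], []
    for s_obj, bad in zip(spectra, flagged):
        if bad:
            s_obj.meta.flags.add("outlier")
            removed.append(s_obj)
        else:
            kept.append(s_obj)
    return kept, removed


def preprocess_dataset(
    dataset: SpectraDataset,
    window: tuple = (315.0, 1800.0),
    baseline_params: BaselineParams | None = None,
    outlier_k: float = 3.0,
    reject_outliers: bool = True,
) -> tuple:
    """Run the full chain on every spectrum of an experiment.

    Outlier rejection happens first, per acquisition map, on the raw
    spectra; survivors are truncated, baseline corrected, and
    area-normalized.  Mean centering is left to the modeling stage
    (the calibration mean must be reused for external data).

    Returns ``(SpectraDataset, PreprocessReport)``.
    """
    baseline_params = baseline_params or BaselineParams()
    removed_ids = []
    survivors = []
    if reject_outliers:
        for (donor, hour), group in dataset.map_groups():
            kept, removed = detect_outliers(group, k=outlier_k)
            survivors.extend(kept)
            removed_ids.extend(
                f"{donor}/h{hour:g}/s{s.meta.spot_index}" for s in removed
            )
    else:
        survivors = list(dataset.spectra)

    processed = []
    for s in survivors:
        t = truncate(s, *window)
        c = correct_baseline(t, baseline_params)
        processed.append(normalize_total_area(c))
    report = PreprocessReport(
        n_input=len(dataset),
        n_removed_outliers=len(removed_ids),
        removed_ids=removed_ids,
        window=tuple(window),
        baseline_params=baseline_params,
    )
    return SpectraDataset(processed), report
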