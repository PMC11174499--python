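"""Latent-variable chemometrics for TSD estimation.

PCA for exploratory structure, NIPALS partial least squares for the two
supervised models — a 3-LV binary PLS-DA classifier (fresh <= 72 h vs
old >= 96 h) and a 5-LV PLSR regressing hour post-deposition — with
interleaved ("Venetian blinds") cross-validation.  The calibration
donor's channel mean is the only centering ever applied to external
data.

The top-level entry is statsmodels-shaped: build a :class:`TSDStudy`
from a preprocessed calibration and validation dataset, call
:meth:`fit`, and read predictions, confusion counts and R^2 values off
the :class:`TSDStudyResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraDataset

__all__ = [
    "PCAModel",
    "LatentModel",
    "ClassRule",
    "pca_fit",
    "pls_fit",
    "pls_predict",
    "plsda_classify",
    "venetian_blinds",
    "cross_validate",
    "TSDStudy",
    "TSDStudyResults",
    "fit_tsd_models",
]


@dataclass
class PCAModel:
    n_components: int
    loadings: np.ndarray  # channels x components, orthonormal columns
    scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray
    train_mean: np.ndarray

    def transform(self, X_new) -> np.ndarray:
        return (np.asarray(X_new, float) - self.train_mean) @ self.loadings


def pca_fit(X, n_components: int, center: bool = True) -> PCAModel:
    """Truncated SVD principal component analysis.

    ``X`` is samples x channels; if ``center`` the column mean is
    removed first and stored.  Components beyond the matrix rank are
    dropped with a warning.
    """
    X = np.asarray(X, float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            RuntimeWarning,
        )
        n_components = max(rank, 1)
    total_var = float((s**2).sum())
    frac = s[:n_components] ** 2 / total_var if total_var > 0 else np.zeros(n_components)
    return PCAModel(
        n_components=n_components,
        loadings=Vt[:n_components].T,
        scores=U[:, :n_components] * s[:n_components],
        explained_variance_fraction=frac,
        train_mean=mu,
    )


@dataclass
class LatentModel:
    """Fitted NIPALS PLS model (single response).

    ``regression_coefficients`` reproduce the fitted linear map from
    centered X to centered y; ``train_mean_x`` / ``train_mean_y`` are
    the calibration means applied to any new data.
    """

    n_lv: int
    x_weights: np.ndarray  # channels x LV (W)
    x_loadings: np.ndarray  # channels x LV (P)
    y_loadings: np.ndarray  # 1 x LV (q)
    x_scores: np.ndarray  # samples x LV (T)
    regression_coefficients: np.ndarray  # channels
    train_mean_x: np.ndarray
    train_mean_y: float


def pls_fit(X, y, n_lv: int, center: bool = True) -> LatentModel:
    """NIPALS partial least squares with X-deflation (PLS1).

    Per latent variable: weight w = X'y / ||X'y||, score t = Xw,
    loading p = X't / t't, response loading q = y't / t't, then deflate
    X by t p'.  The regression vector is B = W (P'W)^{-1} q.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("row count of X must match length of y")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    mu_x = X.mean(axis=0) if center else np.zeros(X.shape[1])
    mu_y = float(y.mean()) if center else 0.0
    Xc = X - mu_x
    yc = y - mu_y
    if np.allclose(yc, 0):
        raise ValueError("zero-variance response")

    max_lv = min(X.shape[0] - 1 if center else X.shape[0], X.shape[1])
    if n_lv > max_lv:
        warnings.warn(
            f"n_lv={n_lv} exceeds usable rank {max_lv}; truncating", RuntimeWarning
        )
        n_lv = max_lv

    n, m = Xc.shape
    W = np.zeros((m, n_lv))
    P = np.zeros((m, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xd = Xc.copy()
    actual = 0
    for a in range(n_lv):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14 * max(1.0, np.abs(Xd).max()):
            warnings.warn(
                f"response variance exhausted after {a} latent variables",
                RuntimeWarning,
            )
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p = Xd.T @ t / tt
        q_a = float(yc @ t) / tt
        Xd -= np.outer(t, p)
        W[:, a], P[:, a], q[a], T[:, a] = w, p, q_a, t
        actual += 1
    if actual == 0:
        raise ValueError("no latent variable could be extracted")
    W, P, q, T = W[:, :actual], P[:, :actual], q[:actual], T[:, :actual]
    B = W @ np.linalg.solve(P.T @ W, q)
    return LatentModel(
        n_lv=actual,
        x_weights=W,
        x_loadings=P,
        y_loadings=q.reshape(1, -1),
        x_scores=T,
        regression_coefficients=B,
        train_mean_x=mu_x,
        train_mean_y=mu_y,
    )


def pls_predict(model: LatentModel, X_new) -> np.ndarray:
    """Apply the stored calibration means, then the regression vector."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.train_mean_x.size:
        raise ValueError(
            f"channel count {X_new.shape[1]} does not match training "
            f"({model.train_mean_x.size})"
        )
    return (X_new - model.train_mean_x) @ model.regression_coefficients + model.train_mean_y


@dataclass
class ClassRule:
    """Binary fresh/old decision on the continuous PLS-DA response.

    Responses are coded fresh = 0, old = 1; a spectrum is called "old"
    when its predicted response exceeds 0.5 (ties break toward
    "fresh"), and no spectrum is ever left unassigned.  The 0.40
    ``hour_misclass_threshold`` is used downstream to flag whole hours.
    """

    class_labels: tuple = ("fresh", "old")
    decision_threshold: float = 0.5
    hour_misclass_threshold: float = 0.40

    def __post_init__(self):
        if not 0.0 < self.hour_misclass_threshold < 1.0:
            raise ValueError("hour_misclass_threshold must lie in (0, 1)")


def plsda_classify(model: LatentModel, X_new, rule: ClassRule | None = None):
    """Classify spectra; returns ``(labels, continuous_response)``."""
    rule = rule or ClassRule()
    resp = pls_predict(model, X_new)
    labels = np.where(resp > rule.decision_threshold, rule.class_labels[1], rule.class_labels[0])
    return labels, resp


def venetian_blinds(n_samples: int, n_splits: int):
    """Interleaved CV folds: fold j holds indices i with i mod n_splits == j."""
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if n_splits > n_samples:
        raise ValueError("n_splits cannot exceed n_samples")
    return [np.arange(j, n_samples, n_splits) for j in range(n_splits)]


def cross_validate(X, y, n_lv: int, n_splits: int = 10) -> np.ndarray:
    """Venetian-blinds held-out predictions, refit (and re-centered) per fold."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    n_splits = min(n_splits, n)
    preds = np.empty(n)
    for fold in venetian_blinds(n, n_splits):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if not mask.any():
            raise ValueError("empty training fold")
        model = pls_fit(X[mask], y[mask], n_lv)
        preds[fold] = pls_predict(model, X[fold])
    return preds


# ---------------------------------------------------------------------------
# The two-donor TSD study


@dataclass
class TSDStudyConfig:
    plsda_lv: int = 3
    plsr_lv: int = 5
    cv_splits: int = 10
    class_boundary: tuple = (72.0, 96.0)
    log_time: bool = False
    rule: ClassRule = field(default_factory=ClassRule)


class TSDStudy:
    """Calibration-donor / validation-donor TSD modeling study.

    Parameters
    ----------
    train, test : SpectraDataset
        Preprocessed (truncated, baseline-corrected, area-normalized)
        spectra with hour labels.  ``train`` is the calibration donor,
        ``test`` the external-validation donor.
    config : TSDStudyConfig
    """

    def __init__(self, train: SpectraDataset, test: SpectraDataset,
                 config: TSDStudyConfig | None = None):
        self.config = config or TSDStudyConfig()
        lo, hi = self.config.class_boundary
        for name, ds in (("train", train), ("test", test)):
            bad = [h for h in ds.schedule if lo < h < hi]
            if bad:
                raise ValueError(
                    f"{name} dataset contains hours {bad} strictly inside the "
                    f"class boundary ({lo}, {hi}); binary class undefined"
                )
        self.train = train
        self.test = test

    def _classes(self, hours: np.ndarray) -> np.ndarray:
        return (hours >= self.config.class_boundary[1]).astype(float)

    def fit(self) -> "TSDStudyResults":
        cfg = self.config
        X_train = self.train.matrix
        X_test = self.test.matrix
        h_train = self.train.hours
        h_test = self.test.hours
        y_train = np.log10(h_train) if cfg.log_time else h_train
        c_train = self._classes(h_train)

        plsda = pls_fit(X_train, c_train, cfg.plsda_lv)
        plsr = pls_fit(X_train, y_train, cfg.plsr_lv)

        n = X_train.shape[0]
        splits = min(cfg.cv_splits, n)
        cv_class_resp = cross_validate(X_train, c_train, cfg.plsda_lv, splits)
        cv_hour_pred = cross_validate(X_train, y_train, cfg.plsr_lv, splits)

        cal_labels, cal_resp = plsda_classify(plsda, X_train, cfg.rule)
        ext_labels, ext_resp = plsda_classify(plsda, X_test, cfg.rule)
        cv_labels = np.where(
            cv_class_resp > cfg.rule.decision_threshold,
            cfg.rule.class_labels[1],
            cfg.rule.class_labels[0],
        )

        cal_hours = plsr.train_mean_y + (X_train - plsr.train_mean_x) @ plsr.regression_coefficients
        ext_hours = pls_predict(plsr, X_test)
        if cfg.log_time:
            cal_hours = 10.0**cal_hours
            ext_hours = 10.0**ext_hours
            cv_hour_pred = 10.0**cv_hour_pred

        return TSDStudyResults(
            study=self,
            plsda=plsda,
            plsr=plsr,
            class_true={"calibration": c_train, "cv": c_train, "external": self._classes(h_test)},
            class_labels={"calibration": cal_labels, "cv": cv_labels, "external": ext_labels},
            class_response={"calibration": cal_resp, "cv": cv_class_resp, "external": ext_resp},
            hour_true={"calibration": h_train, "cv": h_train, "external": h_test},
            hour_pred={"calibration": cal_hours, "cv": cv_hour_pred, "external": ext_hours},
        )


class TSDStudyResults:
    """Fitted PLS-DA / PLSR models and their per-set predictions.

    Sets are ``calibration`` (train refit), ``cv`` (Venetian-blinds
    held-out) and ``external`` (validation donor).  Negative predicted
    hours are reported as-is and flagged, never clipped.
    """

    def __init__(self, study, plsda, plsr, class_true, class_labels,
                 class_response, hour_true, hour_pred):
        self.study = study
        self.plsda = plsda
        self.plsr = plsr
        self.class_true = class_true
        self.class_labels = class_labels
        self.class_response = class_response
        self.hour_true = hour_true
        self.hour_pred = hour_pred

    @property
    def sets(self):
        return ("calibration", "cv", "external")

    def accuracy(self, which: str = "external") -> float:
        rule = self.study.config.rule
        true_lab = np.where(
            self.class_true[which] == 1.0, rule.class_labels[1], rule.class_labels[0]
        )
        return float(np.mean(true_lab == self.class_labels[which]))

    def r_squared(self, which: str) -> float:
        a = self.hour_true[which]
        p = self.hour_pred[which]
        return 1.0 - float(np.sum((a - p) ** 2) / np.sum((a - a.mean()) ** 2))

    @property
    def n_negative_hour_predictions(self) -> int:
        return int(sum((self.hour_pred[s] < 0).sum() for s in self.sets))

    def summary(self) -> str:
        cfg = self.study.config
        lines = [
            "Two-donor TSD study",
            f"  PLS-DA: {self.plsda.n_lv} LV, classes fresh <= {cfg.class_boundary[0]:g} h "
            f"/ old >= {cfg.class_boundary[1]:g} h",
            f"  PLSR:   {self.plsr.n_lv} LV, response = "
            + ("log10(hour)" if cfg.log_time else "hour"),
        ]
        for s in self.sets:
            lines.append(
                f"  {s:<12s} accuracy = {100 * self.accuracy(s):5.1f}%   "
                f"R^2(hour) = {self.r_squared(s):6.3f}"
            )
        if self.n_negative_hour_predictions:
            lines.append(
                f"  note: {self.n_negative_hour_predictions} negative hour "
                "predictions (reported unclipped)"
            )
        return "\n".join(lines)


def fit_tsd_models(train: SpectraDataset, test: SpectraDataset,
                   config: TSDStudyConfig | None = None) -> TSDStudyResults:
    """Functional wrapper: ``TSDStudy(train, test, config).fit()``."""
    return TSDStudy(train, test, config).fit()
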