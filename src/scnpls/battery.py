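"""Cognitive battery preparation: imputation and confound residualization.

The neuropsychological battery is a subjects x 17-tests table spanning five
cognitive domains (attention, executive, language, memory, visuospatial),
with a small fraction of missing cells.  Missing scores are completed by an
iterative auto-scaled low-rank (trimmed-scores style) PLS imputation: start
from column means, z-score each test on its observed cells, repeatedly
re-estimate the missing cells from a rank-k model of the completed matrix
until the imputed values stop moving.

Confound control replaces each outcome column by its unstandardized
ordinary-least-squares residuals against an intercept plus the nuisance
design (age, sex, handedness, log infarct volume, total intracranial
volume, and — for longitudinal change scores — the scan interval).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    AlignmentError,
    CollinearityWarning,
    DataError,
    DimensionError,
    UninformativeTestError,
)

DOMAINS = ("attention", "executive", "language", "memory", "visuospatial")

#: The default 17-test battery: (test, domain, direction).  Timed tests
#: (trail-making, reaction times) score "higher_worse"; accuracy scores
#: "higher_better".
DEFAULT_TESTS: tuple[tuple[str, str, str], ...] = (
    ("digit_span", "attention", "higher_better"),
    ("tmt_a", "attention", "higher_worse"),
    ("simple_rt", "attention", "higher_worse"),
    ("choice_rt", "attention", "higher_worse"),
    ("tmt_b", "executive", "higher_worse"),
    ("digit_symbol", "executive", "higher_better"),
    ("letter_number", "executive", "higher_better"),
    ("bnt", "language", "higher_better"),
    ("cowat_animals", "language", "higher_better"),
    ("cowat_fas", "language", "higher_better"),
    ("hvlt_immediate", "memory", "higher_better"),
    ("hvlt_delay", "memory", "higher_better"),
    ("hvlt_recognition", "memory", "higher_better"),
    ("rcf_delay", "memory", "higher_better"),
    ("rcf_copy", "visuospatial", "higher_better"),
    ("cdt", "visuospatial", "higher_better"),
    ("jlo", "visuospatial", "higher_better"),
)

DEFAULT_CONFOUNDS = ("age", "sex", "handedness", "log_infarct_volume", "tiv")


@dataclasses.dataclass
class CognitiveBattery:
    """Subjects x tests score table with domain and direction metadata.

    Missing cells are NaN in ``scores``; ``missing_mask`` is derived.
    """

    subject_ids: list[str]
    test_names: list[str]
    scores: np.ndarray
    domain: dict[str, str]
    direction: dict[str, str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.subject_ids), len(self.test_names)):
            raise DimensionError("scores shape does not match ids/tests")
        for t in self.test_names:
            if t not in self.domain:
                raise DataError(f"test {t!r} has no domain label")
            if self.direction.get(t) not in ("higher_better", "higher_worse"):
                raise DataError(f"test {t!r} has no valid direction")
        if np.isinf(self.scores).any():
            raise DataError("scores contain infinite values")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.scores)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.subject_ids, columns=self.test_names)

    def copy_with_scores(self, scores: np.ndarray) -> "CognitiveBattery":
        return CognitiveBattery(
            subject_ids=list(self.subject_ids),
            test_names=list(self.test_names),
            scores=np.array(scores, dtype=float),
            domain=dict(self.domain),
            direction=dict(self.direction),
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        domain: Mapping[str, str],
        direction: Mapping[str, str],
    ) -> "CognitiveBattery":
        return cls(
            subject_ids=[str(i) for i in frame.index],
            test_names=[str(c) for c in frame.columns],
            scores=frame.to_numpy(dtype=float),
            domain=dict(domain),
            direction=dict(direction),
        )


@dataclasses.dataclass
class ConfoundTable:
    """Per-subject nuisance variables used for residualization."""

    subject_ids: list[str]
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.subject_ids):
            raise DimensionError("confound rows do not match subject_ids")
        if self.frame.isna().any().any():
            raise DataError("confound table contains missing values")

    def design(self, columns: Sequence[str]) -> np.ndarray:
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise DataError(f"confound columns not present: {missing}")
        return self.frame.loc[:, list(columns)].to_numpy(dtype=float)


def log_transform_volume(volume_mm3: np.ndarray) -> np.ndarray:
    """log(volume + 1 mm^3); keeps zero infarct volumes finite."""
    v = np.asarray(volume_mm3, dtype=float)
    if (v < 0).any():
        raise DataError("infarct volumes must be non-negative")
    return np.log1p(v)


class PLSImputer(TransformerMixin, BaseEstimator):
    """Iterative auto-scaled low-rank imputation of missing battery cells.

    Missing cells start at the observed column mean; each iteration
    z-scores every column of the current completed matrix (the auto-scaling
    statistics are recomputed as the imputations move), replaces the
    missing cells by a rank-``n_components`` SVD reconstruction, and stops
    once the largest absolute change of any imputed cell (in auto-scaled
    units) drops below ``tol``.  Observed cells are never modified and
    values are returned on the original scale.

    The procedure is deterministic; ``random_state`` is accepted for
    interface symmetry with the stochastic estimators.

    Attributes
    ----------
    n_iter_ : iterations run
    converged_ : whether the change criterion was met before ``max_iter``
    trace_ : per-iteration max absolute change of imputed cells
    """

    def __init__(
        self,
        n_components: int = 2,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: None = None) -> "PLSImputer":
        self.fit_transform(X)
        return self

    def fit_transform(self, X: np.ndarray, y: None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DimensionError("expected a 2D matrix")
        n, q = X.shape
        missing = np.isnan(X)
        fully_missing = np.flatnonzero(missing.all(axis=0))
        if fully_missing.size:
            raise UninformativeTestError(
                f"columns with no observed values: {fully_missing.tolist()}"
            )
        if self.n_components >= min(n, q):
            raise DataError("n_components must be < min(n_subjects, n_tests)")

        self.trace_ = []
        if not missing.any():
            self.n_iter_ = 0
            self.converged_ = True
            return X.copy()

        # mean start, then iterate: auto-scale the completed matrix, rebuild
        # the missing cells from the rank-k model, rescale — re-computing the
        # scaling statistics every iteration as the imputations move
        out = X.copy()
        out[missing] = np.broadcast_to(np.nanmean(X, axis=0), X.shape)[missing]
        for it in range(1, self.max_iter + 1):
            mean = out.mean(axis=0)
            sd = out.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            Z = (out - mean) / sd
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            k = self.n_components
            recon = U[:, :k] @ (s[:k, None] * Vt[:k])
            delta = np.max(np.abs(recon[missing] - Z[missing]))
            out[missing] = (recon * sd + mean)[missing]
            self.trace_.append(float(delta))
            if delta < self.tol:
                self.n_iter_ = it
                self.converged_ = True
                break
        else:
            self.n_iter_ = self.max_iter
            self.converged_ = False
            warnings.warn(
                f"imputation did not converge in {self.max_iter} iterations "
                f"(last change {self.trace_[-1]:.3g})",
                UserWarning,
            )
        return out

    def transform(self, X: np.ndarray) -> np.ndarray:
        # stateless completion: each table is completed on its own model
        return self.fit_transform(X)


def impute_battery(
    battery: CognitiveBattery,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    rng_seed: int | None = None,
) -> tuple[CognitiveBattery, dict]:
    """Complete a battery's missing cells; returns the battery and a trace.

    The trace records per-iteration maximal change of the imputed cells (in
    auto-scaled units) and a convergence flag.
    """
    imputer = PLSImputer(
        n_components=n_components, tol=tol, max_iter=max_iter, random_state=rng_seed
    )
    completed = imputer.fit_transform(battery.scores)
    trace = {
        "n_iter": imputer.n_iter_,
        "converged": bool(imputer.converged_),
        "max_abs_change": [float(d) for d in imputer.trace_],
        "n_imputed_cells": int(battery.missing_mask.sum()),
    }
    return battery.copy_with_scores(completed), trace


class ConfoundRegressor(TransformerMixin, BaseEstimator):
    """Replace outcomes by unstandardized OLS residuals against confounds.

    ``fit(X)`` learns, column by column, the least-squares fit of ``X`` on
    an intercept plus the confound design supplied at construction;
    ``transform(X)`` returns ``X`` minus the fitted values.  A rank-deficient
    design triggers a :class:`CollinearityWarning` and falls back to the
    minimum-norm solution (which ``lstsq`` provides).
    """

    def __init__(self, confounds: np.ndarray | None = None):
        self.confounds = confounds

    def _design(self, n: int) -> np.ndarray:
        if self.confounds is None:
            return np.ones((n, 1))
        C = np.asarray(self.confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise AlignmentError("confound rows do not match outcome rows")
        return np.c_[np.ones(n), C]

    def fit(self, X: np.ndarray, y: None = None) -> "ConfoundRegressor":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        D = self._design(X.shape[0])
        if D.shape[0] <= D.shape[1]:
            raise DataError("need more subjects than design columns")
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            warnings.warn(
                "confound design is rank-deficient; using minimum-norm "
                "least squares",
                CollinearityWarning,
            )
        self.coef_, *_ = np.linalg.lstsq(D, X, rcond=None)
        self.design_rank_ = int(rank)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        D = self._design(X.shape[0])
        resid = X - D @ self.coef_
        return resid[:, 0] if squeeze else resid


def confound_design(
    confounds: ConfoundTable,
    include_scan_interval: bool = False,
    columns: Sequence[str] | None = None,
) -> np.ndarray:
    """The nuisance design matrix (without intercept) for one epoch.

    ``columns`` overrides the default confound set (age, sex, handedness,
    log infarct volume, TIV); ``include_scan_interval`` appends the scan
    interval for longitudinal change scores.
    """
    if columns is None:
        columns = list(DEFAULT_CONFOUNDS)
    else:
        columns = list(columns)
    if include_scan_interval and "scan_interval" not in columns:
        columns.append("scan_interval")
    return confounds.design(columns)


def residualize(
    values: np.ndarray,
    confounds: ConfoundTable,
    include_scan_interval: bool = False,
    columns: Sequence[str] | None = None,
) -> np.ndarray:
    """Unstandardized OLS residuals of each column of ``values``."""
    design = confound_design(confounds, include_scan_interval, columns)
    reg = ConfoundRegressor(confounds=design)
    return reg.fit(values).transform(values)
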