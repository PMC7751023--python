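"""Two-block PLS correlation: the engine behind seed PLS and behavioural PLS.

Given two subject-aligned blocks X (n x p, e.g. voxels) and Y (n x q, e.g.
seed means or test scores), the method decomposes the cross-block matrix

    R = Y_c' X_c / (n - 1)        (q x p; columns mean-centred, optionally
                                   unit-variance scaled)

by singular value decomposition R = U S V'.  Each latent variable (LV)
pairs a left salience (column of V, over X features — the "brain salience")
with a right salience (column of U, over Y features) and a singular value.
Subject-level scores are the projections of the centred blocks onto their
saliences.  Inference is non-parametric:

* permutation test — Y rows are randomly reordered ``n_perm`` times, the
  model refit, and each LV's singular value compared with its null
  distribution (add-one p-values);
* bootstrap — subjects are resampled with replacement ``n_boot`` times and
  each salience element's stability summarized as original value divided by
  its bootstrap standard error (the bootstrap ratio, BSR; |BSR| >= 2 is the
  conventional contribution criterion), with percentile 95% intervals for
  the feature-score loadings.

The SVD sign is arbitrary; every LV is oriented so the largest-magnitude
right-salience element is positive, and bootstrap replicates are aligned to
the original saliences by sign (optionally by orthogonal Procrustes).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy.linalg import orthogonal_procrustes
from sklearn.base import BaseEstimator

from .exceptions import DataError, DimensionError, NumericalError
from .gm_maps import GMDataset, SeedMatrix

BSR_CONTRIBUTION_THRESHOLD = 2.0


@dataclasses.dataclass
class PLSResult:
    """All fitted quantities of a two-block PLS correlation model."""

    left_saliences: np.ndarray  # p x L
    right_saliences: np.ndarray  # q x L
    singular_values: np.ndarray  # L
    left_scores: np.ndarray  # n x L
    right_scores: np.ndarray  # n x L
    variance_explained: np.ndarray  # L, sums to 1
    perm_p: np.ndarray | None = None  # L
    latent_r: np.ndarray | None = None  # L, corr(left, right scores)
    latent_r_perm_p: np.ndarray | None = None
    left_bootstrap_ratios: np.ndarray | None = None  # p x L
    right_bootstrap_ratios: np.ndarray | None = None  # q x L
    left_loading_ci: np.ndarray | None = None  # p x L x 2
    right_loading_ci: np.ndarray | None = None  # q x L x 2
    n_infinite_bsr: int = 0
    n_perm: int = 0
    n_boot: int = 0
    rng_seed: int | None = None

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)

    def to_dict(self) -> dict:
        """JSON-serializable summary (arrays as nested lists)."""

        def conv(v):
            if isinstance(v, np.ndarray):
                return np.where(np.isfinite(v), v, np.sign(v) * 1e308).tolist() \
                    if v.dtype.kind == "f" else v.tolist()
            return v

        return {
            f.name: conv(getattr(self, f.name))
            for f in dataclasses.fields(self)
        }


def _as2d(block: np.ndarray, name: str) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if block.ndim != 2:
        raise DimensionError(f"{name} must be 2D")
    return block


def _preprocess(block: np.ndarray, scaling: str, name: str) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if block.ndim != 2:
        raise DimensionError(f"{name} must be 2D")
    centred = block - block.mean(axis=0)
    if scaling == "covariance":
        return centred
    if scaling == "correlation":
        sd = block.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise DataError(
                f"{name} column(s) {zero.tolist()} have zero variance under "
                "correlation scaling"
            )
        return centred / sd
    raise DataError(f"unknown scaling {scaling!r}")


def cross_block(
    X: np.ndarray, Y: np.ndarray, scaling: str = "covariance"
) -> np.ndarray:
    """q x p cross-block matrix Y_c' X_c / (n-1) of mean-centred blocks.

    With ``scaling='correlation'`` both blocks are additionally scaled to
    unit variance, so the entries are Pearson correlations.
    """
    Xc = _preprocess(X, scaling, "X")
    Yc = _preprocess(Y, scaling, "Y")
    if Xc.shape[0] != Yc.shape[0]:
        raise DimensionError("X and Y must have the same number of rows")
    n = Xc.shape[0]
    if n < 3:
        raise DataError("need at least 3 subjects")
    return Yc.T @ Xc / (n - 1)


def _svd_cross(Xc: np.ndarray, Yc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the cross-block of already-preprocessed blocks.

    Returns (V p x L, s, U q x L) with the sign convention applied.
    """
    n = Xc.shape[0]
    R = Yc.T @ Xc / (n - 1)
    try:
        U, s, Vt = sla.svd(R, full_matrices=False, lapack_driver="gesdd")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise NumericalError(f"SVD did not converge: {exc}") from None
    V = Vt.T
    # orient each LV: largest-|u| element of the right salience positive
    for l in range(len(s)):
        j = int(np.argmax(np.abs(U[:, l])))
        if U[j, l] < 0:
            U[:, l] *= -1
            V[:, l] *= -1
    return V, s, U


class PLSCorrelation(BaseEstimator):
    """Two-block PLS correlation with permutation and bootstrap inference.

    Parameters
    ----------
    scaling : 'covariance' or 'correlation'
        Column preprocessing of both blocks before the cross-block SVD.
        Covariance scaling (mean-centring only) suits homogeneous units such
        as GM probabilities; correlation scaling suits heterogeneous test
        batteries.
    n_perm, n_boot : number of permutations / bootstrap resamples (0 skips
        the corresponding inference; when nonzero, at least 100 each).
    align : 'sign' or 'procrustes'
        How bootstrap replicate saliences are matched to the original ones.
    compute_loading_ci : also collect percentile 95% CIs of the
        feature-vs-opposite-score correlations across resamples.
    confounds : optional n x k nuisance design (no intercept column).
        When given, both blocks are replaced by their OLS residuals against
        an intercept plus these columns before the decomposition, and —
        crucially — the permutation test permutes the *raw* Y rows and
        re-residualizes inside every permutation (Freedman-Lane style), and
        the bootstrap re-estimates the nuisance fit within every resample.
        Permuting already-residualized rows of two blocks that share one
        nuisance design is anti-conservative: both residual blocks live in
        the same (n-k-1)-dimensional subspace, which row shuffling
        destroys, so the permuted singular values run systematically small.
    random_state : seed for the shared permutation/bootstrap streams.

    Fitted attributes use scikit-learn conventions (``x_saliences_``,
    ``singular_values_``, ``perm_p_``, ...).
    """

    def __init__(
        self,
        scaling: str = "covariance",
        n_perm: int = 0,
        n_boot: int = 0,
        align: str = "sign",
        compute_loading_ci: bool = True,
        confounds: np.ndarray | None = None,
        random_state: int | None = None,
    ):
        self.scaling = scaling
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.align = align
        self.compute_loading_ci = compute_loading_ci
        self.confounds = confounds
        self.random_state = random_state

    # ------------------------------------------------------- nuisance model
    def _design(self, n: int) -> np.ndarray | None:
        if self.confounds is None:
            return None
        C = np.asarray(self.confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise DimensionError("confound rows do not match block rows")
        return np.c_[np.ones(n), C]

    @staticmethod
    def _residual(block: np.ndarray, D: np.ndarray | None) -> np.ndarray:
        if D is None:
            return block
        coef, *_ = np.linalg.lstsq(D, block, rcond=None)
        return block - D @ coef

    # ------------------------------------------------------------------ fit
    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PLSCorrelation":
        X = _as2d(X, "X")
        Y = _as2d(Y, "Y")
        if X.shape[0] != Y.shape[0]:
            raise DimensionError("X and Y must have the same number of rows")
        n = X.shape[0]
        if n < 3:
            raise DataError("need at least 3 subjects")
        self._X_raw, self._Y_raw = X, Y
        self._D = D = self._design(n)
        Xc = _preprocess(self._residual(X, D), self.scaling, "X")
        Yc = _preprocess(self._residual(Y, D), self.scaling, "Y")
        self._Xc, self._Yc = Xc, Yc
        V, s, U = _svd_cross(Xc, Yc)
        self.x_saliences_ = V
        self.y_saliences_ = U
        self.singular_values_ = s
        self.x_scores_ = Xc @ V
        self.y_scores_ = Yc @ U
        total = float(np.sum(s**2))
        if total == 0:
            raise DataError("cross-block matrix is identically zero")
        self.variance_explained_ = s**2 / total
        self.latent_r_ = self._latent_r(self.x_scores_, self.y_scores_)

        ss = np.random.SeedSequence(self.random_state)
        perm_ss, boot_ss = ss.spawn(2)
        self.perm_p_ = None
        self.latent_r_perm_p_ = None
        if self.n_perm:
            self._permutation(perm_ss)
        self.x_bootstrap_ratios_ = None
        self.y_bootstrap_ratios_ = None
        self.x_loading_ci_ = None
        self.y_loading_ci_ = None
        self.n_infinite_bsr_ = 0
        if self.n_boot:
            self._bootstrap(boot_ss)
        return self

    @staticmethod
    def _latent_r(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        out = np.empty(xs.shape[1])
        for l in range(xs.shape[1]):
            sx, sy = xs[:, l].std(), ys[:, l].std()
            out[l] = (
                np.nan
                if sx == 0 or sy == 0
                else float(np.corrcoef(xs[:, l], ys[:, l])[0, 1])
            )
        return out

    # ---------------------------------------------------------- permutation
    def _permutation(self, seed_seq: np.random.SeedSequence) -> None:
        if self.n_perm < 100:
            raise DataError("n_perm must be at least 100")
        rng = np.random.default_rng(seed_seq)
        n, L = self._Xc.shape[0], len(self.singular_values_)
        exceed = np.zeros(L)
        r_exceed = np.zeros(L)
        obs_r = np.abs(self.latent_r_)
        # single permutation stream: Y rows reordered, X fixed; the same
        # permutations serve every LV and the latent-correlation null.
        # With a nuisance design, the raw Y is permuted and re-residualized
        # inside the loop (Freedman-Lane) so the null respects the design.
        for _ in range(self.n_perm):
            perm = rng.permutation(n)
            if self._D is None:
                Yp = self._Yc[perm]
            else:
                resid = self._residual(self._Y_raw[perm], self._D)
                Yp = _preprocess(resid, self._safe_scaling(resid), "Y")
            Vp, sp, Up = _svd_cross(self._Xc, Yp)
            exceed += sp >= self.singular_values_ - 1e-12
            rp = self._latent_r(self._Xc @ Vp, Yp @ Up)
            with np.errstate(invalid="ignore"):
                r_exceed += np.abs(rp) >= obs_r - 1e-12
        self.perm_p_ = (1.0 + exceed) / (self.n_perm + 1.0)
        self.latent_r_perm_p_ = (1.0 + r_exceed) / (self.n_perm + 1.0)

    # ------------------------------------------------------------ bootstrap
    def _bootstrap(self, seed_seq: np.random.SeedSequence) -> None:
        if self.n_boot < 100:
            raise DataError("n_boot must be at least 100")
        n = self._Xc.shape[0]
        if n < 10:
            raise DataError("bootstrap needs at least 10 subjects")
        rng = np.random.default_rng(seed_seq)
        p, q = self.x_saliences_.shape[0], self.y_saliences_.shape[0]
        L = len(self.singular_values_)
        vs = np.empty((self.n_boot, p, L))
        us = np.empty((self.n_boot, q, L))
        want_ci = self.compute_loading_ci
        if want_ci:
            x_load = np.empty((self.n_boot, p, L))
            y_load = np.empty((self.n_boot, q, L))
        # resample paired subject rows, refit the nuisance model (if any)
        # and re-centre/re-scale within each resample
        for b in range(self.n_boot):
            idx = rng.integers(0, n, n)
            Db = None if self._D is None else self._D[idx]
            Xr = self._residual(self._X_raw[idx], Db)
            Yr = self._residual(self._Y_raw[idx], Db)
            Xb = _preprocess(Xr, self._safe_scaling(Xr), "X")
            Yb = _preprocess(Yr, self._safe_scaling(Yr), "Y")
            Vb, sb, Ub = _svd_cross(Xb, Yb)
            Vb, Ub = self._align(Vb, Ub)
            vs[b], us[b] = Vb, Ub
            if want_ci:
                x_load[b] = _column_score_corr(Xb, Yb @ Ub)
                y_load[b] = _column_score_corr(Yb, Xb @ Vb)
        se_v = vs.std(axis=0, ddof=1)
        se_u = us.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr_v = np.where(se_v > 0, self.x_saliences_ / se_v,
                             np.sign(self.x_saliences_) * np.inf)
            bsr_u = np.where(se_u > 0, self.y_saliences_ / se_u,
                             np.sign(self.y_saliences_) * np.inf)
        self.x_bootstrap_ratios_ = bsr_v
        self.y_bootstrap_ratios_ = bsr_u
        self.n_infinite_bsr_ = int(np.isinf(bsr_v).sum() + np.isinf(bsr_u).sum())
        if want_ci:
            self.x_loading_ci_ = np.stack(
                [np.percentile(x_load, 2.5, axis=0), np.percentile(x_load, 97.5, axis=0)],
                axis=-1,
            )
            self.y_loading_ci_ = np.stack(
                [np.percentile(y_load, 2.5, axis=0), np.percentile(y_load, 97.5, axis=0)],
                axis=-1,
            )

    def _safe_scaling(self, block: np.ndarray) -> str:
        # a bootstrap resample can produce a constant column even under
        # correlation scaling; fall back to centring for that resample
        if self.scaling == "correlation" and (block.std(axis=0, ddof=1) == 0).any():
            return "covariance"
        return self.scaling

    def _align(self, V: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.align == "procrustes":
            Q, _ = orthogonal_procrustes(U, self.y_saliences_)
            return V @ Q, U @ Q
        flip = np.sign(np.sum(U * self.y_saliences_, axis=0))
        flip[flip == 0] = 1.0
        return V * flip, U * flip

    # -------------------------------------------------------------- helpers
    def result(self) -> PLSResult:
        return PLSResult(
            left_saliences=self.x_saliences_,
            right_saliences=self.y_saliences_,
            singular_values=self.singular_values_,
            left_scores=self.x_scores_,
            right_scores=self.y_scores_,
            variance_explained=self.variance_explained_,
            perm_p=self.perm_p_,
            latent_r=self.latent_r_,
            latent_r_perm_p=self.latent_r_perm_p_,
            left_bootstrap_ratios=self.x_bootstrap_ratios_,
            right_bootstrap_ratios=self.y_bootstrap_ratios_,
            left_loading_ci=self.x_loading_ci_,
            right_loading_ci=self.y_loading_ci_,
            n_infinite_bsr=self.n_infinite_bsr_,
            n_perm=self.n_perm,
            n_boot=self.n_boot,
            rng_seed=self.random_state,
        )


def _column_score_corr(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """corr(block column j, score column l) for all j, l; NaN-safe for
    constant columns (returned as 0)."""
    Bc = block - block.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    bs = Bc.std(axis=0)
    ss = Sc.std(axis=0)
    denom = np.outer(bs, ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Bc.T @ Sc) / (block.shape[0] * denom)
    return np.where(denom > 0, r, 0.0)


# ----------------------------------------------------------- thin wrappers


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    scaling: str = "covariance",
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
    align: str = "sign",
) -> PLSResult:
    """Fit a two-block PLS correlation model; see :class:`PLSCorrelation`."""
    est = PLSCorrelation(
        scaling=scaling,
        n_perm=n_perm,
        n_boot=n_boot,
        align=align,
        random_state=rng_seed,
    )
    return est.fit(X, Y).result()


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 5000,
    rng_seed: int | None = None,
    scaling: str = "covariance",
) -> np.ndarray:
    """Add-one permutation p-value per LV (Y rows permuted, X fixed)."""
    return fit_pls(X, Y, scaling=scaling, n_perm=n_perm, rng_seed=rng_seed).perm_p


def bootstrap_stability(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 1000,
    rng_seed: int | None = None,
    scaling: str = "covariance",
    align: str = "sign",
) -> PLSResult:
    """Bootstrap ratios and loading CIs for the saliences of X-vs-Y PLS."""
    return fit_pls(
        X, Y, scaling=scaling, n_boot=n_boot, rng_seed=rng_seed, align=align
    )


def latent_correlation(result: PLSResult, lv_index: int = 0) -> tuple[float, float | None]:
    """Pearson r of left vs right scores of one LV and its permutation p."""
    if not 0 <= lv_index < result.n_lv:
        raise DataError(f"lv_index {lv_index} out of range")
    ls = result.left_scores[:, lv_index]
    rs = result.right_scores[:, lv_index]
    if len(ls) < 3:
        raise NumericalError("correlation undefined for fewer than 3 subjects")
    if ls.std() == 0 or rs.std() == 0:
        raise NumericalError("correlation undefined for zero-variance scores")
    r = float(np.corrcoef(ls, rs)[0, 1])
    p = None
    if result.latent_r_perm_p is not None:
        p = float(result.latent_r_perm_p[lv_index])
    return r, p


def derive_scn(
    gm: GMDataset,
    seed_block: SeedMatrix | np.ndarray,
    seed_columns: Sequence[int] | None = None,
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
    scaling: str = "covariance",
    compute_loading_ci: bool = False,
) -> PLSResult:
    """Seed PLS: one structural covariance network from a 1- or 2-seed block.

    X is the subjects x voxels GM block, Y the seed-mean column(s).  LV1's
    left salience is the network's voxelwise covariance pattern (reshape via
    ``gm.unmask``); LV1's left scores are the subjects' brain scores.
    """
    Y = seed_block.values if isinstance(seed_block, SeedMatrix) else np.asarray(seed_block)
    if Y.ndim == 1:
        Y = Y[:, None]
    if seed_columns is not None:
        Y = Y[:, list(seed_columns)]
    if Y.shape[1] not in (1, 2):
        raise DataError("seed block must have 1 or 2 columns")
    est = PLSCorrelation(
        scaling=scaling,
        n_perm=n_perm,
        n_boot=n_boot,
        random_state=rng_seed,
        compute_loading_ci=compute_loading_ci,
    )
    return est.fit(gm.data, Y).result()
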