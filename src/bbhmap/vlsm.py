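"""Mass-univariate voxel-wise lesion-symptom mapping (VLSM).

For every analyzed voxel v the outcome is regressed on
``[1, lesion_v, covariates]`` by ordinary least squares; the lesion
coefficient's t statistic (df = n - p), a one-tailed p value and the matching
standard-normal z score form the statistical maps. Voxels enter the analysis
only if covered by at least ``min_coverage`` subjects. Family-wise error is
controlled with Bonferroni over the analyzed voxels.

The per-voxel regressions share every regressor except the lesion indicator,
so the whole map is computed in closed form via Frisch-Waugh-Lovell
partialling: residualize the outcome and all lesion columns on the shared
regressors once, then each voxel reduces to a simple regression between
residuals. This is algebraically identical to fitting each voxel's OLS
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .grids import VolumeGrid

__all__ = [
    "LesionMatrix",
    "VLSMResult",
    "VoxelLesionSymptomMapper",
    "build_lesion_matrix",
    "vlsm_map",
    "threshold_map",
]


@dataclass
class LesionMatrix:
    """Subjects x analyzed-voxels binary matrix plus the voxel bookkeeping.

    ``voxel_index`` holds the flat (C-order) grid index of each matrix column;
    ``grid_shape``/``affine`` allow scattering column statistics back into
    template space.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("lesion matrix must be 2D (subjects x voxels)")
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        if self.voxel_index.shape[0] != self.values.shape[1]:
            raise ValueError("voxel_index length must equal the column count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def scatter(self, column_values: np.ndarray, fill=np.nan) -> VolumeGrid:
        """Place per-column values back onto the full grid (fill elsewhere)."""
        flat = np.full(int(np.prod(self.grid_shape)), fill, dtype=float)
        flat[self.voxel_index] = column_values
        return VolumeGrid(flat.reshape(self.grid_shape), self.affine, self.space_tag)

    def analyzed_mask(self) -> VolumeGrid:
        flat = np.zeros(int(np.prod(self.grid_shape)), dtype=np.uint8)
        flat[self.voxel_index] = 1
        return VolumeGrid(flat.reshape(self.grid_shape), self.affine, self.space_tag)


@dataclass
class VLSMResult:
    """Per-voxel statistical maps and the thresholds that go with them."""

    t_map: VolumeGrid
    z_map: VolumeGrid
    p_map: VolumeGrid
    analyzed_mask: VolumeGrid
    n_analyzed_voxels: int
    alpha: float
    corrected_threshold: float
    correction: str
    tail: str
    df: int
    n_degenerate: int


def build_lesion_matrix(
    masks: list[VolumeGrid], min_coverage: int = 5
) -> LesionMatrix:
    """Stack binary masks and keep voxels covered by >= min_coverage subjects."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    n = len(masks)
    flat = np.empty((n, int(np.prod(first.shape))), dtype=np.uint8)
    for i, m in enumerate(masks):
        first.require_same_lattice(m, "lesion-matrix inputs")
        if not m.is_binary():
            raise ValueError("lesion masks must be binary")
        flat[i] = m.data.reshape(-1)
    coverage = flat.sum(axis=0, dtype=np.int64)
    keep = np.flatnonzero(coverage >= min_coverage)
    if keep.size == 0:
        raise ValueError(
            f"no voxel is covered by >= {min_coverage} subjects "
            f"(maximum coverage seen: {int(coverage.max(initial=0))})"
        )
    return LesionMatrix(
        values=flat[:, keep],
        voxel_index=keep,
        grid_shape=first.shape,
        affine=first.affine,
        space_tag=first.space_tag,
    )


class VoxelLesionSymptomMapper(BaseEstimator):
    """Voxel-wise lesion-symptom mapping as a scikit-learn style estimator.

    Parameters
    ----------
    tail : {"greater", "less"}
        Direction of the one-tailed test on the lesion coefficient;
        "greater" tests that lesion presence increases the outcome.
    alpha : float
        Family-wise significance level.
    correction : {"none", "bonferroni"}
        Multiple-comparison correction across analyzed voxels.
    min_coverage : int
        Minimum number of subjects with signal for a voxel to be analyzed
        (used when ``fit`` receives raw masks rather than a LesionMatrix).

    Attributes (after ``fit``)
    --------------------------
    result_ : VLSMResult
    t_, p_, z_ : ndarray, per analyzed voxel (column order of the matrix)
    n_analyzed_voxels_ : int
    corrected_threshold_ : float
    """

    def __init__(
        self,
        tail: str = "greater",
        alpha: float = 0.05,
        correction: str = "bonferroni",
        min_coverage: int = 5,
    ) -> None:
        self.tail = tail
        self.alpha = alpha
        self.correction = correction
        self.min_coverage = min_coverage

    def _validate(self) -> None:
        if self.tail not in ("greater", "less"):
            raise ValueError("tail must be 'greater' or 'less'")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError("correction must be 'none' or 'bonferroni'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def fit(self, X, y, covariates: np.ndarray | None = None):
        """Fit the voxel-wise maps.

        X may be a LesionMatrix, a list of binary VolumeGrids, or a plain
        (n_subjects, n_voxels) binary array; y is the per-subject outcome
        (binary outcomes are dummy coded 0/1 and analyzed with the same
        linear model). Covariates, if given, are (n_subjects, k).
        """
        self._validate()
        if isinstance(X, LesionMatrix):
            matrix = X
        elif isinstance(X, (list, tuple)) and X and isinstance(X[0], VolumeGrid):
            matrix = build_lesion_matrix(list(X), self.min_coverage)
        else:
            X = np.asarray(X)
            matrix = LesionMatrix(
                values=X,
                voxel_index=np.arange(X.shape[1]),
                grid_shape=(1, 1, X.shape[1]),
                affine=np.eye(4),
            )
        y = np.asarray(y, dtype=float).reshape(-1)
        n = matrix.n_subjects
        if y.shape[0] != n:
            raise ValueError(f"outcome length {y.shape[0]} != n_subjects {n}")
        if np.ptp(y) == 0:
            raise ValueError("outcome is constant: no variance to model")

        if covariates is None:
            Z = np.ones((n, 1))
        else:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                covariates = covariates.T
            Z = np.column_stack([np.ones(n), covariates])
        q = Z.shape[1]
        df = n - q - 1
        if df <= 0:
            raise ValueError("not enough subjects for the requested model")

        # Frisch-Waugh-Lovell partialling on the shared regressors
        Q, _ = np.linalg.qr(Z)
        L = matrix.values.astype(float)
        ey = y - Q @ (Q.T @ y)
        EL = L - Q @ (Q.T @ L)

        sxx = np.einsum("ij,ij->j", EL, EL)
        sxy = ey @ EL
        syy = float(ey @ ey)
        degenerate = sxx <= max(1e-12, 1e-12 * n)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(degenerate, np.nan, sxy / sxx)
            rss = syy - np.where(degenerate, 0.0, beta**2 * sxx)
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / df / sxx)
            t = beta / se
        t[degenerate] = np.nan

        if self.tail == "greater":
            p = stats.t.sf(t, df)
        else:
            p = stats.t.cdf(t, df)
        with np.errstate(invalid="ignore"):
            z = stats.norm.isf(p)
        if self.tail == "less":
            z = -z

        n_vox = matrix.n_voxels
        corrected = (
            self.alpha / n_vox if self.correction == "bonferroni" else self.alpha
        )

        self.matrix_ = matrix
        self.t_, self.p_, self.z_ = t, p, z
        self.beta_ = beta
        self.df_ = df
        self.n_analyzed_voxels_ = n_vox
        self.corrected_threshold_ = corrected
        self.n_degenerate_ = int(degenerate.sum())
        self.result_ = VLSMResult(
            t_map=matrix.scatter(t),
            z_map=matrix.scatter(z),
            p_map=matrix.scatter(p),
            analyzed_mask=matrix.analyzed_mask(),
            n_analyzed_voxels=n_vox,
            alpha=self.alpha,
            corrected_threshold=corrected,
            correction=self.correction,
            tail=self.tail,
            df=df,
            n_degenerate=self.n_degenerate_,
        )
        return self

    def transform(self, X=None) -> VLSMResult:
        """Return the fitted result (X is ignored; sklearn pipeline shim)."""
        if not hasattr(self, "result_"):
            raise AttributeError("mapper is not fitted")
        return self.result_


def vlsm_map(
    matrix: LesionMatrix,
    outcome,
    covariates=None,
    tail: str = "greater",
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> VLSMResult:
    """Functional wrapper over :class:`VoxelLesionSymptomMapper`."""
    mapper = VoxelLesionSymptomMapper(tail=tail, alpha=alpha, correction=correction)
    return mapper.fit(matrix, outcome, covariates=covariates).result_


def threshold_map(
    result: VLSMResult, alpha: float | None = None, correction: str | None = None
) -> VolumeGrid:
    """Binary suprathreshold map at an (optionally corrected) alpha level."""
    alpha = result.alpha if alpha is None else alpha
    correction = result.correction if correction is None else correction
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if correction == "bonferroni":
        cut = alpha / result.n_analyzed_voxels
    elif correction == "none":
        cut = alpha
    else:
        raise ValueError("correction must be 'none' or 'bonferroni'")
    p = result.p_map.data
    if alpha >= 1 and correction == "none":
        supra = np.isfinite(p)
    else:
        supra = p < cut
    return result.p_map.with_data(supra.astype(np.uint8))
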