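"""Predict voxelwise function from connectivity fingerprints.

For each subject, a voxelwise linear regression relates the functional
contrast value of every region voxel to its connectivity fingerprint (an
intercept plus the column-z-scored streamline counts to each cortical
target).  Under leave-one-out cross-validation the regression coefficients
of the n-1 training subjects are averaged (each participant weighted
equally) and applied to the held-out subject's design matrix; accuracy is
the Pearson correlation between the z-scored prediction and the z-scored
observed map.  A functional group-average predictor — the mean of the
training subjects' z-scored maps — serves as a benchmark that captures
spatial consistency irrespective of connectivity.

Explained variance is partitioned with semipartial correlations: the unique
R^2 of each predictor is the squared correlation of the observed map with
that prediction orthogonalized with respect to the other, and the shared
component is the two-predictor R^2 minus the sum of unique components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def zscore(values) -> np.ndarray:
    """Z-score with population SD (divisor n); constant input maps to zeros."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("zscore needs at least 2 elements")
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


@dataclass
class DesignMatrix:
    """Intercept column plus column-z-scored connectivity [V x (1 + T)]."""

    X: np.ndarray
    target_names: list = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def build_design(connectivity) -> DesignMatrix:
    """Design matrix from a ConnectivityMatrix (or a raw counts array).

    All-zero (empty-ROI) target columns stay all-zero after z-scoring, so
    they contribute nothing to the fit without producing NaNs.
    """
    counts = getattr(connectivity, "counts", connectivity)
    names = list(getattr(connectivity, "target_names",
                         range(np.asarray(counts).shape[1])))
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 voxels")
    cz = np.column_stack([zscore(counts[:, j])
                          for j in range(counts.shape[1])])
    X = np.column_stack([np.ones(counts.shape[0]), cz])
    return DesignMatrix(X=X, target_names=names)


def fit_voxelwise_weights(X, y) -> np.ndarray:
    """Least-squares weights; minimum-norm solution under rank deficiency."""
    A = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if A.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PredictionResult:
    """Per-subject predictions with accuracy summaries for one contrast."""

    predicted: list
    observed: list
    r: np.ndarray
    mae: np.ndarray
    method: str
    contrast: str
    folds: str = "loo"

    @property
    def n_subjects(self) -> int:
        return len(self.predicted)


def _fold_assignment(n: int, folds) -> list:
    """Held-out index -> training indices, for LOOCV or k-fold CV."""
    if folds in (None, "loo"):
        return [[j for j in range(n) if j != i] for i in range(n)]
    k = int(folds)
    if not 2 <= k <= n:
        raise ValueError(f"folds must be in [2, n_subjects], got {folds}")
    membership = np.array_split(np.arange(n), k)
    train = {}
    for part in membership:
        others = [j for j in range(n) if j not in set(part.tolist())]
        for i in part:
            train[int(i)] = others
    return [train[i] for i in range(n)]


def predict_connectivity_loocv(cohort, contrast: str,
                               folds=None) -> PredictionResult:
    """Cross-validated connectivity-fingerprint prediction of a contrast.

    For each held-out subject, the training subjects' weight vectors are
    averaged elementwise (unweighted: every participant counts equally
    irrespective of voxel count) and applied to the held-out design; the
    z-scored prediction is scored by Pearson r against the z-scored
    observed map.  ``folds=4`` switches to 4-fold CV.
    """
    designs = [build_design(c) for c in cohort.connectivities()]
    observed = [zscore(v) for v in cohort.observed(contrast)]
    n = len(designs)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    betas = [fit_voxelwise_weights(d, y) for d, y in zip(designs, observed)]
    train_sets = _fold_assignment(n, folds)
    predicted, r, mae = [], [], []
    for i in range(n):
        beta_cv = np.mean([betas[j] for j in train_sets[i]], axis=0)
        pred = zscore(designs[i].X @ beta_cv)
        predicted.append(pred)
        r.append(_pearson(pred, observed[i]))
        mae.append(float(np.mean(np.abs(pred - observed[i]))))
    return PredictionResult(predicted=predicted, observed=observed,
                            r=np.array(r), mae=np.array(mae),
                            method="connectivity", contrast=contrast,
                            folds="loo" if folds in (None, "loo")
                            else str(folds))


def predict_group_average_loocv(cohort, contrast: str,
                                folds=None) -> PredictionResult:
    """Functional group-average benchmark prediction of a contrast.

    The prediction for each held-out subject is the z-scored voxelwise mean
    of the training subjects' z-scored observed maps (identity warp: all
    subjects share the synthetic lattice).
    """
    observed = [zscore(v) for v in cohort.observed(contrast)]
    n = len(observed)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    train_sets = _fold_assignment(n, folds)
    predicted, r, mae = [], [], []
    for i in range(n):
        pred = zscore(np.mean([observed[j] for j in train_sets[i]], axis=0))
        predicted.append(pred)
        r.append(_pearson(pred, observed[i]))
        mae.append(float(np.mean(np.abs(pred - observed[i]))))
    return PredictionResult(predicted=predicted, observed=observed,
                            r=np.array(r), mae=np.array(mae),
                            method="group_average", contrast=contrast,
                            folds="loo" if folds in (None, "loo")
                            else str(folds))


def orthogonalize_prediction(pred, other) -> np.ndarray:
    """Residualize ``pred`` on ``other`` (simple regression with intercept).

    The residuals carry only the variance of ``pred`` not shared with
    ``other``.  A constant ``other`` leaves nothing to regress out: the
    mean-centered ``pred`` is returned with a warning.
    """
    pred = np.asarray(pred, dtype=float)
    other = np.asarray(other, dtype=float)
    if pred.shape != other.shape or pred.size < 3:
        raise ValueError("pred and other must share a length >= 3")
    if other.std() == 0:
        warnings.warn("degenerate (constant) regressor: returning "
                      "mean-centered prediction", stacklevel=2)
        return pred - pred.mean()
    A = np.column_stack([np.ones_like(other), other])
    beta, *_ = np.linalg.lstsq(A, pred, rcond=None)
    return pred - A @ beta


@dataclass
class VariancePartition:
    """Unique/shared R^2 components; components sum to the total R^2."""

    unique_conn: float
    unique_group: float
    shared: float
    total: float

    def __post_init__(self):
        resid = self.unique_conn + self.unique_group + self.shared - self.total
        if abs(resid) > 1e-10:
            raise AssertionError(
                f"variance partition identity violated by {resid:.3e}")


def _r_squared(X, y) -> float:
    """R^2 of an OLS fit with intercept."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return 0.0
    return float(1.0 - np.sum(resid ** 2) / tss)


def partition_variance(pred_conn, pred_group, observed) -> VariancePartition:
    """Semipartial variance partition of an observed map on two predictions.

    total: R^2 of the two-predictor regression; unique components: squared
    correlation of the observed map with each prediction orthogonalized on
    the other (squared semipartial correlations); shared: total minus the
    unique components (can be negative under suppression).
    """
    pred_conn = np.asarray(pred_conn, dtype=float)
    pred_group = np.asarray(pred_group, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if not (pred_conn.shape == pred_group.shape == observed.shape) \
            or observed.size < 4:
        raise ValueError("inputs must share a common length >= 4")
    if observed.std() == 0 or (pred_conn.std() == 0 and pred_group.std() == 0):
        raise ValueError("degenerate (constant) inputs")
    ones = np.ones_like(observed)
    total = _r_squared(np.column_stack([ones, pred_conn, pred_group]),
                       observed)
    def _unique(pred, other):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resid = orthogonalize_prediction(pred, other)
        # an all-but-zero residual is pure float noise, not unique variance
        if resid.std() < 1e-10 * max(pred.std(), other.std(), 1.0):
            return 0.0
        return _pearson(observed, resid) ** 2

    uc = _unique(pred_conn, pred_group)
    ug = _unique(pred_group, pred_conn)
    return VariancePartition(unique_conn=uc, unique_group=ug,
                             shared=total - uc - ug, total=total)


@dataclass
class GroupTest:
    """One-sample t-test of per-subject correlations against zero."""

    t: float
    p: float
    mean: float
    ci95: tuple
    n: int


def group_level_test(r_values, alpha: float = 0.05,
                     fisher_z: bool = False) -> GroupTest:
    """Two-tailed one-sample t-test (df = n-1) of r values against zero.

    Tests the raw correlations by default; ``fisher_z=True`` applies
    arctanh first (the reported mean/CI stay on the r scale regardless).
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 values")
    x = np.arctanh(r) if fisher_z else r
    n = r.size
    se = x.std(ddof=1) / np.sqrt(n)
    if se < 1e-12 * max(abs(x.mean()), 1.0):
        t = 0.0 if x.mean() == 0 else float(np.sign(x.mean()) * np.inf)
        p = 1.0 if t == 0 else 0.0
    else:
        t = float(x.mean() / se)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    se_r = r.std(ddof=1) / np.sqrt(n)
    ci = (float(r.mean() - tcrit * se_r), float(r.mean() + tcrit * se_r))
    return GroupTest(t=t, p=p, mean=float(r.mean()), ci95=ci, n=n)


def prediction_table(conn_result: PredictionResult,
                     group_result: PredictionResult,
                     region: str = "synthetic_striatum") -> pd.DataFrame:
    """Per-subject table of full/orthogonalized accuracy and R^2 components."""
    if conn_result.contrast != group_result.contrast:
        raise ValueError("results are for different contrasts")
    rows = []
    for i in range(conn_result.n_subjects):
        obs = conn_result.observed[i]
        pc, pg = conn_result.predicted[i], group_result.predicted[i]
        part = partition_variance(pc, pg, obs)
        rows.append({
            "subject": i, "region": region,
            "contrast": conn_result.contrast,
            "r_conn": conn_result.r[i], "r_group": group_result.r[i],
            "r_conn_orth": _pearson(obs, orthogonalize_prediction(pc, pg)),
            "r_group_orth": _pearson(obs, orthogonalize_prediction(pg, pc)),
            "mae_conn": conn_result.mae[i], "mae_group": group_result.mae[i],
            "unique_conn": part.unique_conn, "unique_group": part.unique_group,
            "shared": part.shared, "total": part.total,
        })
    return pd.DataFrame(rows)


def group_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Group-level summary (mean r, 95% CI, p) per contrast and method."""
    rows = []
    for (region, contrast), df in per_subject.groupby(["region", "contrast"]):
        for method, col, orth_col in (("connectivity", "r_conn",
                                       "r_conn_orth"),
                                      ("group_average", "r_group",
                                       "r_group_orth")):
            full = group_level_test(df[col].to_numpy())
            orth = group_level_test(df[orth_col].to_numpy())
            rows.append({
                "region": region, "contrast": contrast, "method": method,
                "mean_r": full.mean, "ci_lo": full.ci95[0],
                "ci_hi": full.ci95[1], "p": full.p,
                "mean_r_orth": orth.mean, "p_orth": orth.p,
                "unique_r2": df["unique_conn" if method == "connectivity"
                                else "unique_group"].mean(),
                "shared_r2": df["shared"].mean(),
                "total_r2": df["total"].mean(),
                "n": full.n,
            })
    return pd.DataFrame(rows)
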