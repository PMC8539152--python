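"""Re-derivation of group contributions from experimental data.

The training pipeline mirrors the published procedure: a molecules-by-groups
occurrence matrix is built, normalized into its normal-equation form
``(X'X) a = X'y`` and balanced with a Gauss-Seidel coordinate sweep; a
k-fold cross-validation (default ten folds) then yields the cross-validated
standard error S, and compounds deviating from their cross-validated
prediction by more than ``outlier_k * S`` (default three) are discarded.
Solving, cross-validating and discarding repeats until no compound is
rejected.  Accuracy statistics are reported only over compounds all of whose
groups are *valid* (supported by at least ``min_molecules`` training
molecules), which is why the evaluated compound count is smaller than the
fitted one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConvergenceError, NonIdentifiableError
from .graph import Molecule
from .groups import Decomposition, decompose
from .table import ContributionTable

logger = logging.getLogger(__name__)


@dataclass
class TrainingRecord:
    """One compound with its experimental heat of combustion (kJ/mol)."""

    molecule: Union[Molecule, Decomposition]
    hc_exp: float
    name: str = ""


@dataclass
class DesignSystem:
    """Occurrence matrix (M molecules x N groups) with its response vector."""

    X: pd.DataFrame
    y: np.ndarray

    @property
    def labels(self) -> list[str]:
        return list(self.X.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


@dataclass
class FitResult:
    contributions: dict[str, float]
    group_molecules: dict[str, int]
    r2: float
    sigma: float
    sigma_n: float
    avg_dev: float
    mad_percent: float
    n_compounds_fit: int
    n_compounds_evaluated: int


@dataclass
class CVResult:
    q2: float
    s_cv: float
    avg_dev_cv: float
    mad_percent_cv: float
    folds: int
    fold_assignment: np.ndarray
    y_pred_cv: np.ndarray
    n_evaluated: int


def build_design_system(records: Sequence[TrainingRecord],
                        table_vocab: Optional[Sequence[str]] = None,
                        geometry_policy: str = "topology_only") -> tuple[DesignSystem, list[TrainingRecord]]:
    """Occurrence matrix from training records; returns (system, kept records).

    Records whose decomposition contains uncovered atoms are excluded with a
    logged reason.  Vocabulary columns never used by any record are dropped
    with a warning.
    """
    if not records:
        raise ValueError("at least one training record is required")
    rows, kept = [], []
    for rec in records:
        d = (rec.molecule if isinstance(rec.molecule, Decomposition)
             else decompose(rec.molecule, geometry_policy=geometry_policy))
        if d.uncovered_atoms:
            logger.warning("record %r excluded: uncovered atoms %s",
                           rec.name, d.uncovered_atoms)
            continue
        rows.append({k.render(): float(v) for k, v in d.counts.items()})
        kept.append(rec)
    if not rows:
        raise ValueError("no record could be decomposed against the vocabulary")
    frame = pd.DataFrame(rows).fillna(0.0)
    if table_vocab is not None:
        used = [c for c in table_vocab if c in frame.columns]
        missing = [c for c in frame.columns if c not in set(table_vocab)]
        if missing:
            raise ValueError(f"decomposition keys outside the vocabulary: {missing}")
        unused = sorted(set(table_vocab) - set(used))
        if unused:
            warnings.warn(f"{len(unused)} vocabulary columns unused; dropped",
                          stacklevel=2)
        frame = frame.reindex(columns=used, fill_value=0.0)
    if frame.shape[1] == 0:
        raise ValueError("empty vocabulary overlap")
    y = np.array([rec.hc_exp for rec in kept], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite experimental values")
    frame.index = [rec.name or str(i) for i, rec in enumerate(kept)]
    return DesignSystem(frame, y), kept


def gauss_seidel_solve(system: Union[DesignSystem, np.ndarray],
                       y: Optional[np.ndarray] = None,
                       tol: float = 1e-6, max_iter: int = 10_000,
                       x0: Optional[np.ndarray] = None) -> tuple[np.ndarray, dict]:
    """Solve the least-squares problem min ||X a - y|| by Gauss-Seidel.

    The occurrence matrix is normalized into its normal-equation form
    ``(X'X) a = X'y`` and balanced with coordinate sweeps in fixed column
    order starting from zero, until the largest coordinate update falls
    below ``tol`` (kJ/mol).  ``X'X`` is symmetric positive (semi-)definite,
    for which Gauss-Seidel is convergent; an exactly rank-deficient system
    (perfectly collinear group columns) is refused rather than silently
    producing one of its infinitely many solutions.

    Returns the solution and an iteration log ``{"iterations", "max_update"}``.
    """
    if isinstance(system, DesignSystem):
        X = system.X.to_numpy(dtype=float)
        y = system.y
    else:
        X = np.asarray(system, dtype=float)
        y = np.asarray(y, dtype=float)
    m, n = X.shape
    occupied = X.any(axis=0)
    if not occupied.all():
        removed = np.flatnonzero(~occupied)
        logger.warning("removing %d zero-occurrence columns: %s", removed.size, removed)
    G = X.T @ X
    c = X.T @ y
    if np.linalg.matrix_rank(G) < n - int((~occupied).sum()):
        raise NonIdentifiableError(
            "normal-equation matrix is rank deficient (collinear group columns)")
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    active = np.flatnonzero(occupied)
    diag = np.diag(G)
    max_update = np.inf
    for it in range(1, max_iter + 1):
        max_update = 0.0
        for j in active:
            new = (c[j] - G[j] @ x + diag[j] * x[j]) / diag[j]
            max_update = max(max_update, abs(new - x[j]))
            x[j] = new
        if max_update < tol:
            return x, {"iterations": it, "max_update": max_update}
    raise ConvergenceError(
        f"Gauss-Seidel did not converge in {max_iter} sweeps "
        f"(last max update {max_update:.3g} kJ/mol)",
        last_iterate=x, n_iter=max_iter)


class GaussSeidelRegressor(RegressorMixin, BaseEstimator):
    """Linear additive model without intercept, solved by Gauss-Seidel.

    Drop-in scikit-learn regressor: ``fit(X, y)`` stores ``coef_`` (the
    group contributions in kJ/mol), ``predict`` is the plain dot product.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 10_000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        cols = list(X.columns) if hasattr(X, "columns") else None
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=float)
        coef, log = gauss_seidel_solve(Xa, ya, tol=self.tol, max_iter=self.max_iter)
        self.coef_ = coef
        self.n_iter_ = log["iterations"]
        self.max_update_ = log["max_update"]
        self.feature_names_in_ = np.asarray(cols, dtype=object) if cols else None
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


def compute_stats(y_exp: np.ndarray, y_pred: np.ndarray,
                  n_params: Optional[int] = None) -> tuple[float, float, float, float]:
    """(r2, sigma, avg_dev, mad_percent) of a prediction against experiment.

    ``r2`` is the squared Pearson correlation; ``sigma`` uses an ``n - p``
    denominator when the fitted-parameter count ``n_params`` is given and a
    plain ``n`` (residual RMS) otherwise, the cross-validation convention.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1 or y_exp.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if not (np.all(np.isfinite(y_exp)) and np.all(np.isfinite(y_pred))):
        raise ValueError("non-finite values")
    if np.ptp(y_exp) == 0:
        raise ValueError("zero variance in the experimental values: r2 undefined")
    resid = y_exp - y_pred
    if np.allclose(resid, 0):
        r2 = 1.0
    else:
        r2 = float(sstats.pearsonr(y_exp, y_pred).statistic ** 2)
    n = y_exp.size
    denom = n - n_params if n_params is not None else n
    if denom <= 0:
        raise ValueError("more parameters than observations")
    sigma = float(np.sqrt(np.sum(resid ** 2) / denom))
    avg_dev = float(np.mean(np.abs(resid)))
    mad_percent = float(np.mean(np.abs(resid / y_exp)) * 100.0)
    return r2, sigma, avg_dev, mad_percent


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic shuffled split into folds as equal as possible."""
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, folds)):
        assignment[chunk] = fold
    return assignment


def cross_validate(system: DesignSystem, folds: int = 10, seed: int = 0,
                   tol: float = 1e-6, max_iter: int = 10_000) -> CVResult:
    """k-fold cross-validation: every compound is tested exactly once.

    A test compound is evaluable only when all of its groups occur in the
    training folds; others receive NaN predictions and are excluded from the
    statistics (the published tables show the same shrinkage).
    """
    X = system.X.to_numpy(dtype=float)
    y = system.y
    m = X.shape[0]
    if folds < 2 or folds > m:
        raise ValueError("folds must be between 2 and the number of records")
    rng = np.random.default_rng(seed)
    assignment = _fold_assignment(m, folds, rng)
    y_pred = np.full(m, np.nan)
    for fold in range(folds):
        test = assignment == fold
        Xtr, ytr = X[~test], y[~test]
        present = Xtr.any(axis=0)
        coef = np.zeros(X.shape[1])
        coef[present], _ = gauss_seidel_solve(Xtr[:, present], ytr,
                                              tol=tol, max_iter=max_iter)
        evaluable = test & ~(X[:, ~present].any(axis=1) if (~present).any()
                             else np.zeros(m, dtype=bool))
        y_pred[evaluable] = X[evaluable] @ coef
    ok = np.isfinite(y_pred)
    q2, s_cv, avg_cv, mad_cv = compute_stats(y[ok], y_pred[ok])
    return CVResult(q2=q2, s_cv=s_cv, avg_dev_cv=avg_cv, mad_percent_cv=mad_cv,
                    folds=folds, fold_assignment=assignment, y_pred_cv=y_pred,
                    n_evaluated=int(ok.sum()))


class GroupContributionTrainer(BaseEstimator):
    """Full contribution-fitting pipeline with CV-based outlier rejection.

    ``fit(X, y)`` takes an occurrence matrix (``DataFrame`` preferred, group
    keys as columns) and experimental heats of combustion.  Fitted
    attributes: ``contributions_`` (kJ/mol per group), ``fit_result_``,
    ``cv_result_`` (both computed on the surviving compounds), ``outliers_``
    (indices into the original record order) and ``survivors_``.

    Parameters
    ----------
    min_molecules : int
        Validity threshold: accuracy statistics are restricted to compounds
        whose groups all reach this support.
    outlier_k : float
        Rejection threshold in multiples of the cross-validated standard
        error S.
    folds : int
        Cross-validation folds.
    single_pass : bool
        Reject outliers once instead of iterating to a fixed point.
    max_rounds : int
        Safety bound on rejection rounds.
    """

    def __init__(self, min_molecules: int = 3, outlier_k: float = 3.0,
                 folds: int = 10, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 10_000, single_pass: bool = False,
                 max_rounds: int = 25):
        self.min_molecules = min_molecules
        self.outlier_k = outlier_k
        self.folds = folds
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.single_pass = single_pass
        self.max_rounds = max_rounds

    def fit(self, X, y):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        frame = frame.astype(float)
        y = np.asarray(y, dtype=float)
        if len(frame) != y.size:
            raise ValueError("X and y length mismatch")
        if len(frame) < self.folds:
            raise ValueError("need at least as many records as folds")
        survivors = np.arange(len(frame))
        history = []
        for round_no in range(self.max_rounds + 1):
            sub = DesignSystem(frame.iloc[survivors], y[survivors])
            cv = cross_validate(sub, folds=min(self.folds, len(survivors)),
                                seed=self.seed, tol=self.tol, max_iter=self.max_iter)
            resid = np.abs(sub.y - cv.y_pred_cv)
            # floor S at 0.01 kJ/mol: far below any experimental resolution,
            # so solver round-off on noise-free data is never an "outlier"
            s_eff = max(cv.s_cv, 0.01)
            bad = np.flatnonzero(np.isfinite(cv.y_pred_cv)
                                 & (resid > self.outlier_k * s_eff))
            history.append({"round": round_no, "n": len(survivors),
                            "s_cv": cv.s_cv, "rejected": bad.size})
            if bad.size == 0 or self.single_pass:
                break
            survivors = np.delete(survivors, bad)
        else:
            raise ConvergenceError(
                f"outlier rejection did not reach a fixed point in "
                f"{self.max_rounds} rounds: {history}")
        self.rejection_history_ = history
        self.survivors_ = survivors
        self.outliers_ = np.setdiff1d(np.arange(len(frame)), survivors)

        sub = DesignSystem(frame.iloc[survivors], y[survivors])
        coef, _ = gauss_seidel_solve(sub, tol=self.tol, max_iter=self.max_iter)
        labels = sub.labels
        self.contributions_ = dict(zip(labels, coef))
        counts = (sub.X > 0).sum(axis=0)
        self.group_molecules_ = {k: int(v) for k, v in counts.items()}
        valid_groups = {k for k, v in self.group_molecules_.items()
                        if v >= self.min_molecules}
        invalid_cols = [k for k in labels if k not in valid_groups]
        evaluable = ~(sub.X[invalid_cols] > 0).any(axis=1).to_numpy() \
            if invalid_cols else np.ones(len(sub.X), dtype=bool)
        y_fit = sub.X.to_numpy() @ coef
        n_eval = int(evaluable.sum())
        if n_eval >= 2 and np.ptp(sub.y[evaluable]) > 0:
            r2, sigma, avg_dev, madp = compute_stats(
                sub.y[evaluable], y_fit[evaluable],
                n_params=min(len(labels), n_eval - 1))
            _, sigma_n, _, _ = compute_stats(sub.y[evaluable], y_fit[evaluable])
        else:  # degenerate evaluable set
            r2 = sigma = sigma_n = avg_dev = madp = float("nan")
        self.fit_result_ = FitResult(
            contributions=self.contributions_,
            group_molecules=self.group_molecules_,
            r2=r2, sigma=sigma, sigma_n=sigma_n, avg_dev=avg_dev,
            mad_percent=madp, n_compounds_fit=len(survivors),
            n_compounds_evaluated=n_eval)
        self.cv_result_ = cross_validate(sub, folds=min(self.folds, len(survivors)),
                                         seed=self.seed, tol=self.tol,
                                         max_iter=self.max_iter)
        return self

    def predict(self, X):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        coef = np.array([self.contributions_.get(c, 0.0) for c in frame.columns]) \
            if isinstance(X, pd.DataFrame) else np.array(list(self.contributions_.values()))
        return frame.to_numpy(dtype=float) @ coef

    def to_table(self) -> ContributionTable:
        """Fitted contributions as a ContributionTable (occurrence counts
        bookkept from the surviving training set)."""
        frame = pd.DataFrame({
            "atom_type": [k.rsplit(" ", 1)[0] if " " in k else k
                          for k in self.contributions_],
            "neighbors": [k.rsplit(" ", 1)[1] if " " in k else ""
                          for k in self.contributions_],
            "contribution": list(self.contributions_.values()),
            "occurrences": [self.group_molecules_[k] for k in self.contributions_],
            "molecules": [self.group_molecules_[k] for k in self.contributions_],
        })
        return ContributionTable.from_frame(frame, min_molecules=self.min_molecules)


def fit(records: Sequence[TrainingRecord], min_molecules: int = 3,
        outlier_k: float = 3.0, folds: int = 10, rng_seed: int = 0,
        single_pass: bool = False) -> tuple[FitResult, CVResult, np.ndarray]:
    """Convenience wrapper: records in, (FitResult, CVResult, outliers) out."""
    system, kept = build_design_system(records)
    trainer = GroupContributionTrainer(min_molecules=min_molecules,
                                       outlier_k=outlier_k, folds=folds,
                                       seed=rng_seed, single_pass=single_pass)
    trainer.fit(system.X, system.y)
    return trainer.fit_result_, trainer.cv_result_, trainer.outliers_
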