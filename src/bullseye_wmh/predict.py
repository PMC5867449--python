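"""Predicting visual-scale scores from regional WMH burden.

A proportional-odds (cumulative-logit) ordinal regression predicts
consensus scores from either scale-specific aggregate regional loads
("local" features) or the global relative WMH burden. Consensus scores
are rater averages and therefore fractional; every distinct observed
value is treated as one ordered level, which preserves the ordering
without inventing a rounding rule.

The evaluation protocol is stratified 2-fold cross-validation repeated
50 times: per repeat, out-of-fold predictions for all subjects are
compared with the actual consensus by ICC(2,1), and results are
reported as mean (SD) with a percentile interval across repeats.
Stratification bins the outcome into quartiles.

:class:`OrdinalScorePredictor` follows the scikit-learn estimator
protocol (``fit`` / ``predict`` / ``get_params``) and composes with
sklearn model selection; :func:`predict_scores` wraps it in the repeated
CV procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .stats import DegenerateDataError, icc_2_1

__all__ = ["OrdinalScorePredictor", "PredictionResult", "predict_scores"]

log = logging.getLogger(__name__)


class OrdinalScorePredictor(RegressorMixin, BaseEstimator):
    """Proportional-odds cumulative-logit model over observed score levels.

    Each distinct value of ``y`` seen during ``fit`` becomes one ordered
    level; ``predict`` returns the most probable level mapped back to its
    score value, so predictions always lie on the training score lattice.

    Parameters
    ----------
    max_levels
        If the outcome has more distinct values than this, adjacent
        levels are merged by quantile binning before fitting (each merged
        level keeps its member scores' mean as its value). Guards against
        sparsely populated levels at small n.
    maxiter
        Optimizer iteration cap for the statsmodels fit.

    Attributes
    ----------
    levels_ : ndarray
        Ordered score values representable by the fitted model.
    result_ : statsmodels results object, or None for degenerate fits.
    fallback_ : str or None
        Set when the full model could not be fitted ("merged" after a
        level-merge refit, "median" when even that failed).
    """

    def __init__(self, max_levels: int = 24, maxiter: int = 200):
        self.max_levels = max_levels
        self.maxiter = maxiter

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _encode(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        levels, codes = np.unique(y, return_inverse=True)
        return levels, codes

    @staticmethod
    def _merge_levels(y: np.ndarray, n_bins: int) -> np.ndarray:
        """Quantile-merge adjacent outcome levels; values become bin means."""
        ranks = pd.Series(y).rank(method="average")
        bins = pd.qcut(ranks, q=min(n_bins, ranks.nunique()), duplicates="drop")
        merged = pd.Series(y).groupby(bins, observed=True).transform("mean")
        return merged.to_numpy()

    def _try_fit(self, X: np.ndarray, codes: np.ndarray):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(codes, X, distr="logit")
            res = model.fit(method="bfgs", maxiter=self.maxiter, disp=False)
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError("non-finite parameters (separation)")
        return res

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=4)
        y = np.asarray(y, dtype=float)
        work_y = y
        if np.unique(y).size > self.max_levels:
            work_y = self._merge_levels(y, self.max_levels)
        self.levels_, codes = self._encode(work_y)
        self.fallback_ = None
        if self.levels_.size < 2:
            # constant outcome: predict that constant
            self.result_ = None
            self.fallback_ = "median"
            return self
        try:
            self.result_ = self._try_fit(X, codes)
        except Exception as exc:  # separation / non-convergence ladder
            log.info("ordinal fit failed (%s); refitting with merged levels", exc)
            merged = self._merge_levels(y, n_bins=min(5, self.levels_.size))
            self.levels_, codes = self._encode(merged)
            try:
                self.result_ = self._try_fit(X, codes)
                self.fallback_ = "merged"
            except Exception as exc2:
                log.info("merged-level refit failed too (%s); falling back "
                         "to the median level", exc2)
                self.result_ = None
                self.fallback_ = "median"
        return self

    def predict(self, X):
        check_is_fitted(self, "levels_")
        X = validate_data(self, X, reset=False)
        if self.result_ is None:
            med = float(np.median(self.levels_))
            return np.full(X.shape[0], med)
        probs = np.asarray(self.result_.model.predict(self.result_.params, X))
        return self.levels_[np.argmax(probs, axis=1)]

    def predict_proba(self, X):
        check_is_fitted(self, "levels_")
        X = validate_data(self, X, reset=False)
        if self.result_ is None:
            p = np.zeros((X.shape[0], self.levels_.size))
            p[:, np.searchsorted(self.levels_, np.median(self.levels_))] = 1.0
            return p
        return np.asarray(self.result_.model.predict(self.result_.params, X))


@dataclass
class PredictionResult:
    """Repeated-CV prediction quality for one feature set.

    ``icc_per_repeat`` holds one ICC(predicted, actual consensus) per
    repeat; summaries are across repeats.
    """

    icc_per_repeat: np.ndarray
    feature_label: str = "local"
    n_raters: int | None = None
    folds: int = 2
    repeats: int = 50
    seed: int | None = None
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def icc_mean(self) -> float:
        return float(np.mean(self.icc_per_repeat))

    @property
    def icc_sd(self) -> float:
        return float(np.std(self.icc_per_repeat, ddof=1))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.icc_per_repeat, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> str:
        lo, hi = self.ci
        return (f"{self.feature_label}: ICC = {self.icc_mean:.2f} "
                f"({self.icc_sd:.2f}) CI = [{lo:.2f} {hi:.2f}]")


def _stratification_bins(y: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Quartile bins of the outcome used to stratify the folds."""
    ranks = pd.Series(y).rank(method="first")
    return pd.qcut(ranks, q=min(n_bins, ranks.nunique()),
                   labels=False, duplicates="drop").to_numpy()


def predict_scores(features, consensus, folds: int = 2, repeats: int = 50,
                   seed: int | None = None, feature_label: str = "local",
                   n_raters: int | None = None,
                   keep_predictions: bool = False) -> PredictionResult:
    """Repeated stratified k-fold CV of the ordinal score predictor.

    Parameters
    ----------
    features
        Subjects x features matrix (a single global-burden column or the
        scale-specific aggregate loads).
    consensus
        Per-subject consensus (averaged) scores; >= 2 distinct values.
    folds, repeats
        CV geometry; defaults 2 folds x 50 repeats.
    seed
        Seeds fold shuffling; fixed seed gives bit-identical results.

    Returns
    -------
    PredictionResult with one ICC(predicted, actual) per repeat.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(consensus).size != 1:
        X = X.T
    y = np.asarray(consensus, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and consensus must share subjects")
    if X.shape[0] < 20:
        raise ValueError("need >= 20 subjects")
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 distinct consensus levels")

    strata = _stratification_bins(y)
    rng = np.random.default_rng(seed)
    iccs = np.empty(repeats)
    pred_rows = []
    for rep in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        pred = np.full(y.shape, np.nan)
        for train, test in cv.split(X, strata):
            est = OrdinalScorePredictor()
            est.fit(X[train], y[train])
            pred[test] = est.predict(X[test])
        try:
            iccs[rep] = icc_2_1(np.column_stack([pred, y]))
        except DegenerateDataError:
            iccs[rep] = 0.0
        if keep_predictions:
            pred_rows.append(pd.DataFrame({
                "repeat": rep, "subject": np.arange(y.size),
                "predicted": pred, "actual": y}))
    return PredictionResult(
        icc_per_repeat=iccs, feature_label=feature_label, n_raters=n_raters,
        folds=folds, repeats=repeats, seed=seed,
        predictions=pd.concat(pred_rows, ignore_index=True) if pred_rows else None,
    )
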