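"""SVM-RFE feature selection.

A linear support-vector machine is fit on the active feature set, features
are scored by the squared primal weight r_i = w_i^2, and the two lowest-
scoring features are eliminated per iteration until 60 remain.  Blood
pressure is a continuous target, so the linear SVM is used in regression
mode (epsilon-insensitive loss); the primal weight vector plays the role of
w = sum_i a_i y_i x_i of the classification formulation.

Features are median-imputed and z-score standardized once before the loop so
squared weights are comparable across units.  Ties in the score are broken
toward the lower registry index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.svm import LinearSVR
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass
class SVMConfig:
    C: float = 1.0
    epsilon: float = 0.1
    tol: float = 1e-3
    max_iter: int = 30000
    seed: int = 0


@dataclass
class RFEState:
    """Bookkeeping of one elimination run."""

    active: list[int]
    weights: Optional[np.ndarray] = None  # aligned with `active`
    scores: Optional[np.ndarray] = None  # r_i = w_i^2
    eliminated_order: list[tuple[int, list[int]]] = field(default_factory=list)
    iteration: int = 0


@dataclass
class SelectionResult:
    """Retained set, full elimination ranking and provenance."""

    retained: list[int]
    retained_names: list[str]
    ranking: np.ndarray  # 1 = retained; higher = eliminated earlier batches
    eliminated_order: list[tuple[int, list[int]]]
    target: str
    svm_config: SVMConfig

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def fit_linear_weights(X: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None) -> np.ndarray:
    """Primal weight vector of a linear epsilon-SVR on standardized features.

    Zero-variance columns receive weight exactly 0.
    """
    cfg = cfg or SVMConfig()
    if np.unique(y).size < 2:
        raise ValueError("target is constant; linear SVM weights are undefined")
    keep = X.std(axis=0) > 0
    w = np.zeros(X.shape[1])
    if np.any(keep):
        svr = LinearSVR(
            C=cfg.C,
            epsilon=cfg.epsilon,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            random_state=cfg.seed,
            dual=True,
        )
        svr.fit(X[:, keep], y)
        w[keep] = svr.coef_
    return w


def rfe_step(state: RFEState, X: np.ndarray, y: np.ndarray, cfg: SVMConfig, step: int = 2) -> RFEState:
    """One elimination iteration: fit, score, drop the `step` worst features."""
    active = np.asarray(state.active)
    try:
        w = fit_linear_weights(X[:, active], y, cfg)
    except Exception as err:  # noqa: BLE001 - annotate with iteration index
        raise RuntimeError(f"SVM fit failed at RFE iteration {state.iteration + 1}") from err
    scores = w**2
    n_drop = min(step, len(active))
    # stable argsort => ties resolved toward the lower (registry) index
    order = np.argsort(scores, kind="stable")
    drop_local = order[:n_drop]
    dropped = sorted(int(active[i]) for i in drop_local)
    remaining = [int(a) for a in active if int(a) not in set(dropped)]
    return RFEState(
        active=remaining,
        weights=w,
        scores=scores,
        eliminated_order=state.eliminated_order + [(state.iteration + 1, dropped)],
        iteration=state.iteration + 1,
    )


def run_rfe(
    X: np.ndarray,
    y: np.ndarray,
    target_size: int = 60,
    step: int = 2,
    cfg: SVMConfig | None = None,
    target: str = "sbp",
    feature_names: Optional[list[str]] = None,
) -> SelectionResult:
    """Eliminate ``step`` features per iteration until ``target_size`` remain."""
    cfg = cfg or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_features = X.shape[1]
    if target_size > n_features:
        raise ValueError("target_size exceeds the number of features")
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(n_features)]

    # impute + standardize once
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xi = np.where(np.isfinite(X), X, med[None, :])
    mu = Xi.mean(axis=0)
    sd = Xi.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xi - mu) / sd

    # standardize the target for the internal fits: epsilon-insensitive loss
    # with a fixed epsilon is scale-sensitive and mmHg-scale targets condition
    # the solver poorly; the elimination ranking is unaffected by this affine
    # rescaling of y up to solver tolerance
    y_sd = y.std()
    ys = (y - y.mean()) / (y_sd if y_sd > 0 else 1.0)

    state = RFEState(active=list(range(n_features)))
    while len(state.active) > target_size:
        this_step = min(step, len(state.active) - target_size)
        state = rfe_step(state, Xs, ys, cfg, step=this_step)

    ranking = np.ones(n_features, dtype=int)
    rank = 2
    for _, batch in reversed(state.eliminated_order):
        for j in batch:
            ranking[j] = rank
        rank += 1

    return SelectionResult(
        retained=sorted(state.active),
        retained_names=[names[i] for i in sorted(state.active)],
        ranking=ranking,
        eliminated_order=state.eliminated_order,
        target=target,
        svm_config=cfg,
    )


def combine_targets(
    res_sbp: SelectionResult, res_dbp: SelectionResult, mode: str = "merged"
) -> list[int]:
    """Reconcile the two per-target selections into one model input set.

    ``per_target`` returns the union bookkeeping caller-side (two models);
    ``merged`` ranks features by the mean of the two elimination ranks and
    keeps the best ``target_size`` (ties toward the lower index).
    """
    if res_sbp.ranking.shape != res_dbp.ranking.shape:
        raise ValueError("selection results come from different registries")
    if mode == "per_target":
        return sorted(set(res_sbp.retained) | set(res_dbp.retained))
    if mode != "merged":
        raise ValueError(f"unknown combine mode {mode!r}")
    n_keep = res_sbp.n_retained
    mean_rank = (res_sbp.ranking + res_dbp.ranking) / 2.0
    order = np.argsort(mean_rank, kind="stable")
    return sorted(int(i) for i in order[:n_keep])


class SVMRFESelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping :func:`run_rfe`.

    Parameters follow the published protocol: keep 60 of 138 features,
    eliminating the two lowest-scored per iteration.

    Attributes
    ----------
    support_ : bool mask of retained features
    ranking_ : 1 for retained features, increasing with earlier elimination
    result_ : the full :class:`SelectionResult`
    """

    def __init__(
        self,
        n_features_to_select: int = 60,
        step: int = 2,
        C: float = 1.0,
        epsilon: float = 0.1,
        random_state: int = 0,
        target: str = "sbp",
    ):
        self.n_features_to_select = n_features_to_select
        self.step = step
        self.C = C
        self.epsilon = epsilon
        self.random_state = random_state
        self.target = target

    def fit(self, X, y):
        X = validate_data(self, X, ensure_all_finite="allow-nan")
        y = np.asarray(y, dtype=float)
        cfg = SVMConfig(C=self.C, epsilon=self.epsilon, seed=self.random_state)
        self.result_ = run_rfe(
            X,
            y,
            target_size=self.n_features_to_select,
            step=self.step,
            cfg=cfg,
            target=self.target,
        )
        self.ranking_ = self.result_.ranking
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.result_.retained] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
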