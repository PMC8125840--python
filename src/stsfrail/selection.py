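"""Bootstrapped recursive feature elimination (RFE) over logistic models.

The selection procedure ranks candidate sensor-derived features by how much
a logistic frailty classifier suffers when each is left out:

1. the cohort is resampled into ``B`` bootstrap training sets (default 2000,
   stratified by frailty status) paired with their out-of-bag validation
   sets;
2. in each elimination loop, one leave-one-out logistic model is fitted per
   remaining candidate feature on every training set and scored by the area
   under the ROC curve (AUC) on the paired validation set;
3. per-candidate AUCs are averaged over the ``B`` splits;
4. the feature whose *exclusion* model has the highest mean AUC -- i.e. the
   feature the model misses least -- is eliminated;
5. steps 1-4 repeat until a single feature remains.

The final ranking is the reverse elimination order (rank 1 = last survivor).
With ``k`` starting features the procedure performs ``B * sum(j, j=2..k)``
model fits (70,000 for k=8, B=2000).  The optimal subset is the smallest
top-``k`` prefix of the ranking that covers all three frailty phenotypes
(slowness, weakness, exhaustion) and whose own model exceeds the AUC
threshold (default 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, PHENOTYPE_MAP

__all__ = [
    "SelectionConfig",
    "BootstrapSplit",
    "LogisticModel",
    "RFELoop",
    "RFETrace",
    "FeatureRanking",
    "SelectionResult",
    "make_bootstrap_pairs",
    "fit_logistic",
    "leave_one_out_auc",
    "rfe_rank",
    "count_model_fits",
    "select_optimal",
]

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class SelectionConfig:
    """Configuration of the bootstrapped RFE procedure."""

    B: int = 2000
    seed: int = 0
    auc_threshold: float = 0.80
    phenotype_map: Mapping[str, str] = field(default_factory=lambda: dict(PHENOTYPE_MAP))
    stratified: bool = True
    literal_elimination: bool = False

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.auc_threshold < 1:
            raise ValueError("auc_threshold must be in (0, 1)")


@dataclass(frozen=True)
class BootstrapSplit:
    """One bootstrap training multiset and its out-of-bag validation set."""

    train: np.ndarray  # n indices drawn with replacement
    val: np.ndarray  # out-of-bag indices, both classes present


@dataclass(frozen=True)
class LogisticModel:
    """Unpenalised maximum-likelihood logistic regression fit."""

    feature_names: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    converged: bool
    n_iter: int
    se_intercept: float | None = None
    se_coef: np.ndarray | None = None

    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.intercept + X @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X))


@dataclass(frozen=True)
class RFELoop:
    """One elimination loop: candidates, their leave-one-out mean AUCs, and
    the eliminated feature."""

    remaining: tuple[str, ...]
    loo_auc: dict[str, float]
    eliminated: str


@dataclass(frozen=True)
class RFETrace:
    loops: tuple[RFELoop, ...]
    n_loo_fits: int


@dataclass(frozen=True)
class FeatureRanking:
    """RFE ranking: ``features[0]`` is rank 1 (the last survivor).

    ``subset_auc[k]`` is the mean validation AUC of the model built on the
    top-k ranked features, computed on the same bootstrap splits.
    """

    features: tuple[str, ...]
    phenotypes: dict[str, str]
    subset_auc: dict[int, float]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the optimal-subset rule; ``admissible=False`` when no
    prefix of the ranking satisfies both criteria."""

    admissible: bool
    selected: tuple[str, ...]
    k: int
    auc: float


# ---------------------------------------------------------------------------
# bootstrap pairs
# ---------------------------------------------------------------------------

def make_bootstrap_pairs(labels, config: SelectionConfig) -> list[BootstrapSplit]:
    """Draw ``config.B`` bootstrap training/validation (out-of-bag) pairs.

    Training sets are drawn with replacement at full size ``n`` (within each
    class when ``config.stratified``); the validation set is the out-of-bag
    complement, redrawn until it contains both classes.  Each pair has its
    own counter-derived random stream, so changing ``B`` never reshuffles
    earlier pairs.
    """
    y = np.asarray(labels, int)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    idx_by_class = [np.flatnonzero(y == c) for c in classes]

    streams = np.random.SeedSequence(config.seed).spawn(config.B)
    splits = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        for _ in range(_MAX_REDRAWS):
            if config.stratified:
                train = np.concatenate(
                    [rng.choice(idx, size=len(idx), replace=True) for idx in idx_by_class]
                )
            else:
                train = rng.integers(0, n, size=n)
            val = np.setdiff1d(np.arange(n), train)
            if len(val) > 0 and len(np.unique(y[val])) == 2:
                break
        else:  # pragma: no cover - probability ~0 at any realistic n
            raise RuntimeError("could not draw a valid out-of-bag set")
        splits.append(BootstrapSplit(train=train, val=val))
    return splits


# ---------------------------------------------------------------------------
# logistic regression (Newton-Raphson MLE)
# ---------------------------------------------------------------------------

def _irls(A: np.ndarray, y: np.ndarray, max_iter: int, tol: float):
    """Newton-Raphson on the logistic log-likelihood; design A includes the
    intercept column.  Returns (beta, hessian, converged, n_iter)."""
    n, p = A.shape
    beta = np.zeros(p)
    H = np.eye(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(A @ beta, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = A.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (A * w[:, None]).T @ A
        if np.linalg.norm(g, np.inf) < tol * n:
            converged = True
            break
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
    # saturated linear predictors indicate (quasi-)separation: the MLE is
    # not finite and the capped estimate must not be reported as converged
    if np.max(np.abs(A @ beta)) >= 30.0:
        converged = False
    return beta, H, converged, it


def fit_logistic(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    compute_se: bool = True,
) -> LogisticModel:
    """Maximum-likelihood logistic regression (no penalty, with intercept).

    Columns are standardized internally for a well-conditioned Newton solve
    and the coefficients mapped back to the original scale.  Under perfect
    separation the likelihood has no finite maximum; the iteration-capped
    estimate is returned with ``converged=False`` (its scores still order
    subjects, so validation AUCs remain usable).  Standard errors come from
    the inverse observed information.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(y)) != 1:
        X = X.T
    y = np.asarray(y, float)
    n, k = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(k))
    elif len(feature_names) != k:
        raise ValueError("feature_names length mismatch")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    A = np.column_stack([np.ones(n), Z])

    beta_z, H, converged, n_iter = _irls(A, y, max_iter, tol)

    coef = beta_z[1:] / sd
    intercept = beta_z[0] - float(np.sum(beta_z[1:] * mu / sd))

    se_i, se_c = None, None
    if compute_se:
        try:
            cov_z = np.linalg.inv(H + 1e-12 * np.eye(k + 1))
            # transform covariance to the original scale
            T = np.zeros((k + 1, k + 1))
            T[0, 0] = 1.0
            T[0, 1:] = -mu / sd
            T[np.arange(1, k + 1), np.arange(1, k + 1)] = 1.0 / sd
            cov = T @ cov_z @ T.T
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se_i, se_c = float(se[0]), se[1:]
        except np.linalg.LinAlgError:
            pass
    return LogisticModel(
        feature_names=tuple(feature_names),
        intercept=float(intercept),
        coef=coef,
        converged=converged,
        n_iter=n_iter,
        se_intercept=se_i,
        se_coef=se_c,
    )


# ---------------------------------------------------------------------------
# leave-one-out AUCs and recursive elimination
# ---------------------------------------------------------------------------

def _table_matrix(table: pd.DataFrame, features: Sequence[str]):
    X = table.loc[:, list(features)].to_numpy(float)
    y = table["status"].to_numpy(int)
    return X, y

def _mean_val_auc(
    X: np.ndarray, y: np.ndarray, cols: Sequence[int], splits: Sequence[BootstrapSplit]
) -> tuple[float, int]:
    """Mean out-of-bag AUC of the model on the given columns; returns the
    number of model fits performed."""
    from .evaluation import roc_auc

    Xs = X[:, list(cols)]
    aucs = np.empty(len(splits))
    for b, split in enumerate(splits):
        model = fit_logistic(
            Xs[split.train], y[split.train], compute_se=False, tol=1e-7, max_iter=30
        )
        scores = model.linear_predictor(Xs[split.val])
        aucs[b] = roc_auc(scores, y[split.val])
    return float(aucs.mean()), len(splits)


def leave_one_out_auc(
    features: Sequence[str],
    table: pd.DataFrame,
    splits: Sequence[BootstrapSplit],
) -> dict[str, float]:
    """Mean validation AUC of the model excluding each candidate in turn."""
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least 2 candidate features")
    X, y = _table_matrix(table, features)
    out = {}
    for j, name in enumerate(features):
        cols = [i for i in range(len(features)) if i != j]
        out[name], _ = _mean_val_auc(X, y, cols, splits)
    return out


def count_model_fits(n_features: int, B: int) -> int:
    """Total leave-one-out model fits of a full RFE run:
    ``B * sum(k, k=2..n_features)`` (one exclusion model per remaining
    feature per loop, looping while at least two features remain)."""
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if B < 1:
        raise ValueError("B must be >= 1")
    return B * sum(range(2, n_features + 1))


def rfe_rank(
    table: pd.DataFrame,
    features: Sequence[str],
    config: SelectionConfig,
    splits: Sequence[BootstrapSplit] | None = None,
    compute_subset_curve: bool = True,
) -> tuple[RFETrace, FeatureRanking]:
    """Rank candidate features by bootstrapped recursive elimination.

    Per loop, the leave-one-out mean AUCs are computed for every remaining
    candidate and the least informative feature -- the one whose exclusion
    model scores highest -- is eliminated (``config.literal_elimination``
    flips this to eliminate the lowest-AUC exclusion model).  Ties break
    toward the candidate earliest in canonical feature order.  The same
    bootstrap splits are reused across loops and for the per-k subset-AUC
    curve, for comparability.
    """
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least 2 candidate features")
    unknown = set(features) - set(config.phenotype_map)
    if unknown:
        raise ValueError(f"features without phenotype tags: {sorted(unknown)}")
    if splits is None:
        X, y = _table_matrix(table, features)
        splits = make_bootstrap_pairs(y, config)

    canon = {name: i for i, name in enumerate(FEATURE_NAMES)}
    remaining = list(features)
    loops = []
    n_fits = 0
    X, y = _table_matrix(table, features)
    col_of = {name: j for j, name in enumerate(features)}

    while len(remaining) >= 2:
        loo = {}
        for name in remaining:
            cols = [col_of[f] for f in remaining if f != name]
            auc, fits = _mean_val_auc(X, y, cols, splits)
            loo[name] = auc
            n_fits += fits
        pick = max if not config.literal_elimination else min
        best = pick(loo.values())
        ties = [f for f in remaining if loo[f] == best]
        eliminated = min(ties, key=lambda f: canon.get(f, len(canon)))
        loops.append(
            RFELoop(remaining=tuple(remaining), loo_auc=dict(loo), eliminated=eliminated)
        )
        remaining.remove(eliminated)

    ranked = [remaining[0]] + [lp.eliminated for lp in reversed(loops)]
    subset_auc = {}
    if compute_subset_curve:
        for k in range(1, len(ranked) + 1):
            cols = [col_of[f] for f in ranked[:k]]
            subset_auc[k], _ = _mean_val_auc(X, y, cols, splits)

    trace = RFETrace(loops=tuple(loops), n_loo_fits=n_fits)
    ranking = FeatureRanking(
        features=tuple(ranked),
        phenotypes={f: config.phenotype_map[f] for f in ranked},
        subset_auc=subset_auc,
    )
    return trace, ranking


def select_optimal(ranking: FeatureRanking, config: SelectionConfig) -> SelectionResult:
    """Smallest top-k prefix of the ranking covering slowness, weakness and
    exhaustion whose subset model AUC exceeds the threshold."""
    if not ranking.subset_auc:
        raise ValueError("ranking has no per-k subset AUCs")
    needed = {"slowness", "weakness", "exhaustion"}
    for k in range(1, len(ranking.features) + 1):
        subset = ranking.features[:k]
        covered = {ranking.phenotypes[f] for f in subset}
        auc = ranking.subset_auc.get(k)
        if needed <= covered and auc is not None and auc > config.auc_threshold:
            return SelectionResult(admissible=True, selected=subset, k=k, auc=auc)
    return SelectionResult(admissible=False, selected=(), k=0, auc=float("nan"))
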