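"""Feature selection by IRIV, VISSA, and stepwise regression, scored by RMSECV.

All three methods score candidate feature subsets with the cross-validated
root mean squared error (RMSECV) of a partial-least-squares regression that
predicts the numeric grade code (I..IV -> 1..4):

    RMSECV = sqrt( sum (Y - Y_cv)^2 / n )

IRIV repeatedly draws random binary inclusion patterns, compares the RMSECV
distribution of submodels that include each variable against those that
exclude it (Mann-Whitney), classifies variables as strongly/weakly
informative, uninformative, or interfering, drops the latter two, and finishes
with backward elimination. VISSA shrinks per-variable sampling weights toward
0/1 by reweighting with each variable's frequency among the best 5% of 500
weighted random submodels per iteration. SRA is classical forward/backward
stepwise regression on partial-F (t-test) significance.

The PLS used inside RMSECV is a univariate SIMPLS written here: the selection
loops evaluate thousands of tiny PLS fits per run and a lean implementation
keeps them cheap. It is cross-checked against an independent PLS
implementation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.model_selection import KFold

from .exceptions import InputError
from .grading import grade_to_code

__all__ = [
    "SelectionResult",
    "IrivConfig",
    "VissaConfig",
    "SraConfig",
    "rmse",
    "rmsecv",
    "iriv_select",
    "vissa_select",
    "sra_select",
    "select_features",
    "coded_labels",
]


def coded_labels(labels) -> np.ndarray:
    """Map grade labels to the numeric codes 1..4 used by the regression."""
    return np.array([grade_to_code(g) for g in labels], dtype=float)


# ---------------------------------------------------------------------------
# univariate SIMPLS

def _pls1_fit(X: np.ndarray, y: np.ndarray, n_components: int):
    """SIMPLS for a single response; X is autoscaled, y centered.

    Returns (x_mean, x_scale, y_mean, coef) with coef on the scaled X.
    """
    xm = X.mean(axis=0)
    xs = X.std(axis=0, ddof=1)
    xs[xs == 0] = 1.0
    ym = y.mean()
    X0 = (X - xm) / xs
    y0 = y - ym
    n, p = X0.shape
    ncomp = min(n_components, p, n - 1)
    S = X0.T @ y0
    W = np.zeros((p, ncomp))
    Q = np.zeros(ncomp)
    V = np.zeros((p, ncomp))
    a_used = 0
    for a in range(ncomp):
        r = S.copy()
        t = X0 @ r
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            break
        t /= normt
        r /= normt
        p_a = X0.T @ t
        q_a = float(y0 @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v /= nv
        S = S - v * (v @ S)
        W[:, a] = r
        Q[a] = q_a
        V[:, a] = v
        a_used = a + 1
    coef = W[:, :a_used] @ Q[:a_used] if a_used else np.zeros(p)
    return xm, xs, ym, coef


def _pls1_predict(model, X: np.ndarray) -> np.ndarray:
    xm, xs, ym, coef = model
    return ym + ((X - xm) / xs) @ coef


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error, the inner formula of RMSECV."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    n_components: int = 5,
    seed: int = 0,
) -> float:
    """k-fold cross-validated RMSE of the internal PLS regression."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 2:
        raise InputError("k must be >= 2")
    if X.shape[0] != y.shape[0] or X.shape[0] < k:
        raise InputError("need at least k rows and matching X/y lengths")
    yhat = np.empty_like(y)
    for train, test in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        model = _pls1_fit(X[train], y[train], n_components)
        yhat[test] = _pls1_predict(model, X[test])
    return rmse(y, yhat)


def choose_components(
    X: np.ndarray, y: np.ndarray, k: int = 5, max_components: int = 10, seed: int = 0
) -> int:
    """Pick the PLS component count (<= max) minimizing 5-fold RMSECV."""
    X = np.asarray(X, float)
    upper = min(max_components, X.shape[1], X.shape[0] - 1)
    scores = [rmsecv(X, y, k=k, n_components=a, seed=seed) for a in range(1, upper + 1)]
    return int(np.argmin(scores)) + 1


# ---------------------------------------------------------------------------
# shared plumbing

@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection run.

    ``selected`` is the chosen feature-name subset; ``rmsecv_trace`` records
    the retained-set RMSECV per iteration/elimination step; ``history`` holds
    per-variable classifications per IRIV round; ``weights_trace`` holds the
    VISSA sampling-weight matrix per iteration.
    """

    method: str
    selected: list[str]
    rmsecv_trace: list[float]
    seed: int
    history: list[dict[str, str]] = field(default_factory=list)
    weights_trace: list[dict[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": list(self.selected),
            "rmsecv_trace": list(map(float, self.rmsecv_trace)),
            "seed": self.seed,
            "history": self.history,
            "weights_trace": self.weights_trace,
        }


def _split_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if "grade" not in table.columns:
        raise InputError("feature table must carry a 'grade' column")
    names = [c for c in table.columns if c != "grade"]
    if len(names) < 1:
        raise InputError("feature table has no feature columns")
    y = coded_labels(table["grade"])
    if len(np.unique(y)) < 2:
        raise InputError("degenerate label column: a single class")
    return table[names].to_numpy(float), y, names


def _validate(table: pd.DataFrame, min_features: int = 2, min_samples: int = 20):
    X, y, names = _split_table(table)
    if len(names) < min_features:
        raise InputError(f"need at least {min_features} features")
    if X.shape[0] < min_samples:
        raise InputError(f"need at least {min_samples} samples")
    return X, y, names


def _backward_eliminate(
    X: np.ndarray, y: np.ndarray, idx: list[int], k: int, ncomp: int, seed: int,
    rtol: float = 0.005,
) -> tuple[list[int], list[float]]:
    """Greedy removal of variables while RMSECV does not increase.

    "Does not increase" is judged against CV sampling noise with a small
    relative tolerance: a variable whose removal changes RMSECV by less than
    ``rtol`` is indistinguishable from chance and is eliminated.
    """
    current = rmsecv(X[:, idx], y, k=k, n_components=ncomp, seed=seed)
    trace = [current]
    idx = list(idx)
    while len(idx) > 1:
        scores = [
            rmsecv(X[:, idx[:j] + idx[j + 1 :]], y, k=k, n_components=ncomp, seed=seed)
            for j in range(len(idx))
        ]
        j_best = int(np.argmin(scores))
        if scores[j_best] <= current * (1.0 + rtol):
            current = min(scores[j_best], current)
            idx.pop(j_best)
            trace.append(scores[j_best])
        else:
            break
    return idx, trace


# ---------------------------------------------------------------------------
# IRIV

@dataclass(frozen=True)
class IrivConfig:
    n_models: int = 500
    k_folds: int = 5
    p_threshold: float = 0.05
    max_rounds: int = 20
    max_components: int = 10


def iriv_select(
    table: pd.DataFrame, cfg: IrivConfig | None = None, seed: int = 0
) -> SelectionResult:
    """Iteratively retain informative variables.

    Each round draws ``n_models`` random binary inclusion patterns, scores
    every submodel by RMSECV, and classifies each variable by comparing the
    score distribution of submodels that include it against those that exclude
    it: a significant decrease (Mann-Whitney p < 0.05) marks it strongly
    informative, a non-significant decrease weakly informative, a
    non-significant increase uninformative, and a significant increase
    interfering. Uninformative and interfering variables are dropped and the
    rounds repeat until only strong/weak variables remain; backward
    elimination then prunes survivors while RMSECV does not increase.
    """
    cfg = cfg or IrivConfig()
    X, y, names = _validate(table)
    rng = np.random.default_rng(seed)
    ncomp = choose_components(X, y, k=cfg.k_folds, max_components=cfg.max_components,
                              seed=seed)
    idx = list(range(len(names)))
    trace: list[float] = []
    history: list[dict[str, str]] = []

    for _ in range(cfg.max_rounds):
        p = len(idx)
        if p == 1:
            break
        M = rng.random((cfg.n_models, p)) < 0.5
        M[~M.any(axis=1)] = True  # no empty submodel
        scores = np.empty(cfg.n_models)
        for m in range(cfg.n_models):
            cols = [idx[j] for j in range(p) if M[m, j]]
            scores[m] = rmsecv(X[:, cols], y, k=cfg.k_folds,
                               n_components=ncomp, seed=seed)
        classes: dict[str, str] = {}
        keep: list[int] = []
        for j in range(p):
            s_in = scores[M[:, j]]
            s_out = scores[~M[:, j]]
            if len(s_in) == 0 or len(s_out) == 0:
                classes[names[idx[j]]] = "weak"
                keep.append(idx[j])
                continue
            dmean = float(s_out.mean() - s_in.mean())  # >0: inclusion helps
            pval = float(mannwhitneyu(s_in, s_out, alternative="two-sided").pvalue)
            if dmean > 0:
                cls = "strong" if pval < cfg.p_threshold else "weak"
            else:
                cls = "interfering" if pval < cfg.p_threshold else "uninformative"
            classes[names[idx[j]]] = cls
            if cls in ("strong", "weak"):
                keep.append(idx[j])
        history.append(classes)
        if not keep:  # degenerate: keep the single best variable
            warnings.warn("IRIV: no informative variable found; keeping the best one")
            singles = [rmsecv(X[:, [i]], y, k=cfg.k_folds, n_components=1, seed=seed)
                       for i in idx]
            keep = [idx[int(np.argmin(singles))]]
        trace.append(rmsecv(X[:, keep], y, k=cfg.k_folds, n_components=ncomp, seed=seed))
        stable = len(keep) == len(idx)
        idx = keep
        if stable:  # every survivor is strong/weak: classification converged
            break

    idx, elim_trace = _backward_eliminate(X, y, idx, cfg.k_folds, ncomp, seed)
    trace.extend(elim_trace)
    return SelectionResult(
        method="iriv",
        selected=[names[i] for i in idx],
        rmsecv_trace=trace,
        seed=seed,
        history=history,
    )


# ---------------------------------------------------------------------------
# VISSA

@dataclass(frozen=True)
class VissaConfig:
    n_models: int = 500
    elite_fraction: float = 0.05
    initial_weight: float = 0.5
    k_folds: int = 5
    max_iterations: int = 50
    max_components: int = 10
    #: minimum relative elite-RMSECV improvement to keep iterating
    rtol: float = 0.02


def vissa_select(
    table: pd.DataFrame, cfg: VissaConfig | None = None, seed: int = 0
) -> SelectionResult:
    """Variable iterative space shrinkage approach.

    Per iteration, draw ``n_models`` weighted binary submodels (variable j
    included with its current weight, initially 0.5), keep the best
    ``elite_fraction`` by RMSECV, and set each weight to the variable's
    frequency among the elite. Iterate until all weights reach {0, 1} or the
    elite RMSECV stops improving (relative improvement below ``rtol``;
    informative variables fixate at weight 1 within the first iterations,
    while letting the flat phase run on only absorbs noise variables by
    random-walk ratcheting). Variables with final weight 1 are selected; an
    all-noise table where no weight reaches 1 yields an empty selection with
    a warning.
    """
    cfg = cfg or VissaConfig()
    X, y, names = _validate(table)
    rng = np.random.default_rng(seed)
    ncomp = choose_components(X, y, k=cfg.k_folds, max_components=cfg.max_components,
                              seed=seed)
    p = len(names)
    weights = np.full(p, cfg.initial_weight)
    n_elite = max(1, int(round(cfg.n_models * cfg.elite_fraction)))
    trace: list[float] = []
    weights_trace: list[dict[str, float]] = []
    best_so_far = np.inf
    best_weights = weights.copy()

    for _ in range(cfg.max_iterations):
        M = rng.random((cfg.n_models, p)) < weights
        M[~M.any(axis=1), 0] = True  # no empty submodel
        scores = np.empty(cfg.n_models)
        for m in range(cfg.n_models):
            cols = np.flatnonzero(M[m])
            scores[m] = rmsecv(X[:, cols], y, k=cfg.k_folds,
                               n_components=ncomp, seed=seed)
        elite = np.argsort(scores)[:n_elite]
        elite_score = float(scores[elite].mean())
        weights = M[elite].mean(axis=0)
        trace.append(elite_score)
        weights_trace.append(dict(zip(names, map(float, weights))))
        if np.all((weights == 0.0) | (weights == 1.0)):
            best_weights = weights.copy()
            break
        if elite_score < best_so_far * (1.0 - cfg.rtol):
            best_so_far = elite_score
            best_weights = weights.copy()
        else:  # RMSECV stopped improving
            break

    selected = [names[j] for j in np.flatnonzero(best_weights == 1.0)]
    if not selected:
        warnings.warn(
            "VISSA: no variable reached weight 1; the table looks uninformative"
        )
    return SelectionResult(
        method="vissa",
        selected=selected,
        rmsecv_trace=trace,
        seed=seed,
        weights_trace=weights_trace,
    )


# ---------------------------------------------------------------------------
# stepwise regression

@dataclass(frozen=True)
class SraConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10
    k_folds: int = 5


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values of OLS slopes (intercept excluded)."""
    import statsmodels.api as sm

    res = sm.OLS(y, sm.add_constant(X)).fit()
    return np.asarray(res.pvalues)[1:]


def sra_select(
    table: pd.DataFrame, cfg: SraConfig | None = None, seed: int = 0
) -> SelectionResult:
    """Classical stepwise regression on the coded labels.

    Forward step: add the candidate with the smallest slope p-value if it is
    below ``p_enter``. Backward step: remove any included variable whose
    p-value rises above ``p_remove``. Repeats until no change. Deterministic;
    zero-variance columns and candidates that do not increase the design-matrix
    rank (collinear duplicates) are never entered.
    """
    cfg = cfg or SraConfig()
    X, y, names = _validate(table, min_features=1, min_samples=4)
    p = len(names)
    usable = [j for j in range(p) if X[:, j].std() > 0]
    included: list[int] = []
    trace: list[float] = []

    def rank_ok(cols: list[int]) -> bool:
        A = np.column_stack([np.ones(len(y))] + [X[:, c] for c in cols])
        return np.linalg.matrix_rank(A, tol=1e-8) == A.shape[1]

    changed = True
    while changed:
        changed = False
        # forward
        candidates = [j for j in usable if j not in included]
        best_j, best_p = None, np.inf
        for j in candidates:
            cols = included + [j]
            if not rank_ok(cols):
                continue
            pv = _ols_pvalues(X[:, cols], y)[-1]
            if pv < best_p:
                best_p, best_j = pv, j
        if best_j is not None and best_p < cfg.p_enter:
            included.append(best_j)
            changed = True
        # backward
        while len(included) > 0:
            pvals = _ols_pvalues(X[:, included], y)
            worst = int(np.argmax(pvals))
            if pvals[worst] > cfg.p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if included:
            trace.append(rmsecv(X[:, included], y, k=cfg.k_folds,
                                n_components=min(5, len(included)), seed=seed))

    if not included:
        warnings.warn("SRA: no variable met the entry threshold")
    return SelectionResult(
        method="sra",
        selected=[names[j] for j in included],
        rmsecv_trace=trace,
        seed=seed,
    )


def select_features(
    table: pd.DataFrame, method: str, seed: int = 0, cfg=None
) -> SelectionResult:
    """Dispatch to one of the three selection algorithms by name."""
    dispatch = {"iriv": iriv_select, "vissa": vissa_select, "sra": sra_select}
    if method not in dispatch:
        raise InputError(f"unknown selection method {method!r}")
    return dispatch[method](table, cfg, seed)
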