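"""Inferential machinery: correlation screen, group tests, PCR, regression tree, CV.

The regression tree follows the conditional-inference recipe: at every node
each candidate covariate is tested for association with the response using a
permutation Spearman statistic (seeded, 9,999 permutations by default), the
p-values are Bonferroni-adjusted over covariates, and the node splits only
when the best adjusted p-value clears ``alpha`` — so covariate selection is
significance-gated rather than greedy, and variables on incomparable scales
compete fairly.  The winning covariate is split at the cutpoint maximizing the
between-group sum of squares subject to a minimum child size, with the
threshold recorded as the midpoint of the bracketing observed values.

Model validation is k-fold cross-validation with fold assignment stratified by
response deciles ("quantile categorization"), repeated with fresh random folds;
pooled held-out predictions and the true activities are both dichotomized at
50% of wild type to form the confusion matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

DEFAULT_SEED = 20221102
LOF_ACTIVITY = 0.5  # activity <= 0.5 is the positive (LOF) class


# ---------------------------------------------------------------------------
# screens and group tests

def spearman_screen(features: pd.DataFrame, activity) -> pd.DataFrame:
    """Per-covariate Spearman rho and two-sided p against activity.

    Uses average ranks for ties and the t-approximation for the p-value.
    Covariates with < 5 complete pairs or zero variance are flagged and get
    NaN statistics.
    """
    y = pd.Series(np.asarray(activity, dtype=float), index=features.index)
    rows = []
    for name in features.columns:
        x = pd.to_numeric(features[name], errors="coerce")
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 5 or x[ok].nunique() < 2:
            rows.append((name, np.nan, np.nan, n,
                         "too_few" if n < 5 else "constant"))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append((name, float(rho), float(p), n, "ok"))
    return pd.DataFrame(rows, columns=["covariate", "rho", "p", "n", "flag"])


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def welch_t_test(group_a, group_b) -> TTestResult:
    """Two-sided unpaired t-test with Welch's unequal-variance correction."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def two_way_anova(values, factor_a, factor_b) -> dict[str, tuple[float, float]]:
    """Two-factor ANOVA with interaction (Type II sums of squares).

    Returns ``{"a": (F, p), "b": (F, p), "interaction": (F, p)}``.
    Every cell of the two-way layout must hold at least 2 observations.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "a": list(factor_a), "b": list(factor_b)})
    cells = df.groupby(["a", "b"], observed=True).size()
    n_cells = df["a"].nunique() * df["b"].nunique()
    if len(cells) < n_cells or (cells < 2).any():
        raise ValueError("every factor-level cell needs n >= 2")
    fit = ols("value ~ C(a) + C(b) + C(a):C(b)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual layouts emit F=inf warnings
        table = sm.stats.anova_lm(fit, typ=2)
    return {
        "a": (float(table.loc["C(a)", "F"]), float(table.loc["C(a)", "PR(>F)"])),
        "b": (float(table.loc["C(b)", "F"]), float(table.loc["C(b)", "PR(>F)"])),
        "interaction": (float(table.loc["C(a):C(b)", "F"]),
                        float(table.loc["C(a):C(b)", "PR(>F)"])),
    }


# ---------------------------------------------------------------------------
# principal-components regression

@dataclass
class PCRModel:
    """Principal-components regression of activity on standardized covariates."""

    covariates: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # columns = components, eigenvalue-descending
    variance_fractions: np.ndarray
    n_selected: int
    coefficients: np.ndarray      # intercept first, then selected-score betas
    r2: float
    adj_r2: float
    n: int

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        z = (X[self.covariates].to_numpy(dtype=float) - self.means) / self.sds
        return z @ self.loadings[:, :self.n_selected]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.transform(X)
        return self.coefficients[0] + scores @ self.coefficients[1:]

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "variance_fractions": self.variance_fractions.tolist(),
            "n_selected": self.n_selected,
            "loadings": self.loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "r2": self.r2, "adj_r2": self.adj_r2, "n": self.n,
        }


def pc_regression(features: pd.DataFrame, activity,
                  var_threshold: float = 0.75) -> PCRModel:
    """Eigendecompose the covariate correlation matrix, keep the top components
    reaching ``var_threshold`` cumulative variance, regress activity on their scores.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(activity, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 covariates")
    if n <= p:
        raise ValueError("need more observations than covariates")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [features.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant covariates cannot be standardized: {bad}")
    z = (X - means) / sds
    corr = z.T @ z / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    if np.min(eigvals) < 1e-12:
        warnings.warn("correlation matrix is singular; trailing components "
                      "carry no variance", stacklevel=2)
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(p):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    frac = eigvals / eigvals.sum()
    n_selected = int(np.searchsorted(np.cumsum(frac), var_threshold - 1e-12) + 1)
    scores = z @ eigvecs[:, :n_selected]
    design = np.column_stack([np.ones(n), scores])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    k = n_selected
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else float("nan")
    return PCRModel(list(features.columns), means, sds, eigvecs, frac,
                    n_selected, beta, r2, adj, n)


# ---------------------------------------------------------------------------
# permutation-gated recursive partitioning

@dataclass
class TreeNode:
    n: int
    prediction: float            # training-response mean of the node
    members: list[int]
    covariate: str | None = None
    threshold: float | None = None
    p_value: float | None = None  # Bonferroni-adjusted permutation p of the split
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_terminal(self) -> bool:
        return self.left is None

    def to_dict(self, with_members: bool = True) -> dict:
        if self.is_terminal:
            d = {"kind": "terminal", "n": self.n, "prediction": self.prediction}
            if with_members:
                d["members"] = self.members
            return d
        return {"kind": "internal", "n": self.n, "prediction": self.prediction,
                "covariate": self.covariate, "threshold": self.threshold,
                "p_value": self.p_value,
                "left": self.left.to_dict(with_members),
                "right": self.right.to_dict(with_members)}


@dataclass
class TreeModel:
    root: TreeNode
    covariates: list[str]
    alpha: float
    min_node: int
    n_perm: int
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariates for prediction: {missing}")
        out = np.empty(len(X), dtype=float)
        cols = {c: X[c].to_numpy(dtype=float) for c in self.covariates}
        for i in range(len(X)):
            node = self.root
            while not node.is_terminal:
                x = cols[node.covariate][i]
                node = node.left if x <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_terminal else 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def split_covariates(self) -> list[str]:
        """Covariates used at internal nodes, in breadth-first order."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            if not node.is_terminal:
                out.append(node.covariate)
                queue += [node.left, node.right]
        return out

    def to_json(self, with_members: bool = True) -> str:
        return json.dumps({"alpha": self.alpha, "min_node": self.min_node,
                           "n_perm": self.n_perm, "seed": self.seed,
                           "covariates": self.covariates,
                           "root": self.root.to_dict(with_members)},
                          indent=2, sort_keys=True)


def _standardized_ranks(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)  # average ranks for ties
    sd = r.std()
    return np.zeros_like(r) if sd == 0 else (r - r.mean()) / sd


def _association_pvalues(X: np.ndarray, y: np.ndarray, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Permutation p-values of |Spearman rho| per covariate (shared permutations)."""
    n, p = X.shape
    rx = np.column_stack([_standardized_ranks(X[:, j]) for j in range(p)])
    ry = _standardized_ranks(y)
    obs = np.abs(ry @ rx) / n
    perm = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    t = np.abs(perm @ rx) / n
    return (1.0 + (t >= obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1.0)


def _best_cutpoint(x: np.ndarray, y: np.ndarray,
                   min_node: int) -> tuple[float, float] | None:
    """Cutpoint maximizing between-group SS with both children >= min_node."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    csum = np.cumsum(ys)
    total = csum[-1]
    best = None
    for i in range(min_node - 1, n - min_node):
        if xs[i] >= xs[i + 1]:
            continue  # not a real boundary between distinct values
        nl = i + 1
        nr = n - nl
        ss = csum[i] ** 2 / nl + (total - csum[i]) ** 2 / nr
        if best is None or ss > best[0] + 1e-12:
            best = (ss, (xs[i] + xs[i + 1]) / 2.0)
    return None if best is None else (best[1], best[0])


def fit_tree(features: pd.DataFrame, activity, alpha: float = 0.05,
             min_node: int = 7, n_perm: int = 9999,
             seed: int = DEFAULT_SEED) -> TreeModel:
    """Significance-gated recursive partitioning of activity on named covariates."""
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    y = np.asarray(activity, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("tree fitting requires complete covariate rows")
    rng = np.random.default_rng(seed)

    def grow(idx: np.ndarray) -> TreeNode:
        node = TreeNode(n=len(idx), prediction=float(y[idx].mean()),
                        members=[int(i) for i in idx])
        if len(idx) < 2 * min_node or np.ptp(y[idx]) == 0:
            return node
        pvals = _association_pvalues(X[idx], y[idx], n_perm, rng)
        adj = np.minimum(1.0, pvals * len(names))
        j = int(np.argmin(adj))
        if adj[j] > alpha:
            return node
        cut = _best_cutpoint(X[idx, j], y[idx], min_node)
        if cut is None:
            return node
        threshold = cut[0]
        mask = X[idx, j] <= threshold
        node.covariate = names[j]
        node.threshold = float(threshold)
        node.p_value = float(adj[j])
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    root = grow(np.arange(len(y)))
    return TreeModel(root, names, alpha, min_node, n_perm, seed)


def predict_tree(tree: TreeModel, features: pd.DataFrame) -> np.ndarray:
    return tree.predict(features)


# ---------------------------------------------------------------------------
# cross-validation and predictor evaluation

@dataclass
class ConfusionMatrix:
    """Counts with LOF (activity <= 0.5) as the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "n": self.n, "accuracy": self.accuracy}


def confusion_from_calls(called: np.ndarray, positive: np.ndarray) -> ConfusionMatrix:
    called = np.asarray(called, dtype=bool)
    positive = np.asarray(positive, dtype=bool)
    return ConfusionMatrix(tp=int((called & positive).sum()),
                           fp=int((called & ~positive).sum()),
                           tn=int((~called & ~positive).sum()),
                           fn=int((~called & positive).sum()))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator,
                      n_bins: int = 10) -> np.ndarray:
    """Fold labels with response-decile stratification (round-robin dealing)."""
    n = len(y)
    try:
        bins = pd.qcut(y, q=min(n_bins, max(2, n // 2)), labels=False,
                       duplicates="drop")
    except ValueError:
        bins = np.zeros(n, dtype=int)
    bins = np.asarray(bins)
    folds = np.empty(n, dtype=int)
    start = int(rng.integers(k))  # rotate so fold 0 is not systematically larger
    dealt = 0
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        rng.shuffle(idx)
        for i in idx:
            folds[i] = (start + dealt) % k
            dealt += 1
    return folds


@dataclass
class CVResult:
    confusion: ConfusionMatrix
    accuracy: float
    per_repeat_accuracy: list[float]
    actual: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    k: int = 10
    repeats: int = 10

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.to_dict(),
                "accuracy": self.accuracy,
                "per_repeat_accuracy": self.per_repeat_accuracy,
                "per_repeat_mean_accuracy": float(np.mean(self.per_repeat_accuracy)),
                "k": self.k, "repeats": self.repeats}


def crossvalidate(features: pd.DataFrame, activity, k: int = 10,
                  repeats: int = 10, seed: int = DEFAULT_SEED,
                  alpha: float = 0.05, min_node: int = 7, n_perm: int = 9999,
                  stratify: bool = True,
                  lof_activity: float = LOF_ACTIVITY) -> CVResult:
    """Repeated k-fold CV of the regression tree; pooled held-out confusion matrix.

    Each repeat draws fresh decile-stratified folds (90% train / 10% test for
    k=10); predictions are pooled over all repeats and dichotomized at the LOF
    activity threshold alongside the true activities.
    """
    y = np.asarray(activity, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("cross-validation needs n >= 20")
    rng = np.random.default_rng(seed)
    actual_all, pred_all, per_repeat = [], [], []
    for _ in range(repeats):
        if stratify:
            folds = _stratified_folds(y, k, rng)
        else:
            folds = np.arange(n) % k
            rng.shuffle(folds)
        rep_actual, rep_pred = [], []
        for fold in range(k):
            test = folds == fold
            tree = fit_tree(features.loc[~test], y[~test], alpha=alpha,
                            min_node=min_node, n_perm=n_perm,
                            seed=int(rng.integers(2**31)))
            rep_actual.append(y[test])
            rep_pred.append(tree.predict(features.loc[test]))
        rep_actual = np.concatenate(rep_actual)
        rep_pred = np.concatenate(rep_pred)
        rep_cm = confusion_from_calls(rep_pred <= lof_activity,
                                      rep_actual <= lof_activity)
        per_repeat.append(rep_cm.accuracy)
        actual_all.append(rep_actual)
        pred_all.append(rep_pred)
    actual = np.concatenate(actual_all)
    predicted = np.concatenate(pred_all)
    cm = confusion_from_calls(predicted <= lof_activity, actual <= lof_activity)
    return CVResult(cm, cm.accuracy, per_repeat, actual, predicted, k, repeats)


PREDICTOR_RULES = {
    # program -> (call function, human-readable rule)
    "fathmm": (lambda s: s <= -0.75, "disease iff score <= -0.75"),
    "polyphen2": (lambda s: s > 0.8, "damaging iff score > 0.8"),
    "opai": (lambda s: s >= 0.95, "oncogenic iff score >= 0.95"),
}


@dataclass
class PredictorEvaluation:
    program: str
    confusion: ConfusionMatrix
    quadrant: pd.Series = field(repr=False)   # TP/FP/TN/FN or 'excluded'
    n_excluded: int = 0
    categories: pd.Series | None = field(default=None, repr=False)

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    def to_dict(self) -> dict:
        d = {"program": self.program, "confusion": self.confusion.to_dict(),
             "accuracy": self.accuracy, "n_excluded": self.n_excluded}
        if self.categories is not None:
            d["category_counts"] = self.categories.value_counts().to_dict()
        return d


def evaluate_predictor(scores, is_lof, program: str) -> PredictorEvaluation:
    """Default-threshold classification of an external predictor against labels.

    ``is_lof`` marks the experimentally loss-of-function variants (GOF and
    neutral count as not-LOF).  Variants with a missing score are excluded
    from the counts but reported.
    """
    if program not in PREDICTOR_RULES:
        raise ValueError(f"unknown program {program!r}")
    call_fn, _ = PREDICTOR_RULES[program]
    s = pd.Series(np.asarray(scores, dtype=float))
    lof = np.asarray(is_lof, dtype=bool)
    present = s.notna().to_numpy()
    called = np.zeros(len(s), dtype=bool)
    called[present] = call_fn(s[present].to_numpy())
    quad = np.where(called & lof, "TP", np.where(called & ~lof, "FP",
                    np.where(~called & lof, "FN", "TN")))
    quad = pd.Series(np.where(present, quad, "excluded"), index=s.index)
    cm = confusion_from_calls(called[present], lof[present])
    categories = None
    if program == "polyphen2":
        cat = np.where(s > 0.8, "probably_damaging",
                       np.where(s >= 0.2, "possibly_damaging", "benign"))
        categories = pd.Series(np.where(present, cat, "missing"), index=s.index)
    return PredictorEvaluation(program, cm, quad,
                               int((~present).sum()), categories)


def actual_vs_predicted_r2(actual, predicted, n_params: int = 1) -> float:
    """Adjusted R-squared of the least-squares fit of actual on predicted."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    n = len(a)
    if n <= n_params + 1:
        raise ValueError("need n > n_params + 1")
    if np.ptp(p) == 0:
        warnings.warn("predicted values have zero variance; R^2 set to 0",
                      stacklevel=2)
        return 0.0
    design = np.column_stack([np.ones(n), p])
    beta, *_ = np.linalg.lstsq(design, a, rcond=None)
    resid = a - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((a - a.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
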