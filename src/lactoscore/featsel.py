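"""Five-algorithm hub-gene selection on a labeled survival cohort.

Four selectors classify the binary label (LASSO-logistic, random forest,
Boruta, gradient boosting) and one models survival (univariate Cox), the only
reading under which all five apply to one cohort. Their outputs are
intersected into the final hub-gene list; the intersection is by construction
a subset of every per-algorithm list.

The Cox solver and Boruta are implemented here from first principles; the
random-forest importance is Breiman's out-of-bag permutation importance on a
hand-rolled bootstrap ensemble of CART trees, shared between select_rf and
Boruta so both rank features by the same statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortTable

__all__ = [
    "SelectionReport",
    "select_lasso",
    "select_unicox",
    "select_rf",
    "select_boruta",
    "select_xgb",
    "intersect_selections",
    "run_feature_selection",
]


@dataclass
class SelectionReport:
    selections: dict[str, list[str]] = field(default_factory=dict)
    diagnostics: dict[str, object] = field(default_factory=dict)
    intersection: list[str] = field(default_factory=list)
    subset_intersections: dict[str, list[str]] = field(default_factory=dict)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


# ---------------------------------------------------------------- LASSO ----


def select_lasso(
    cohort: CohortTable,
    n_folds: int = 10,
    n_repeats: int = 10,
    n_lambdas: int = 30,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """L1-logistic selection at the minimum cross-validated deviance.

    The regularization path is evaluated by repeated stratified k-fold CV;
    the per-repeat lambda at minimum mean deviance is averaged (in log
    space) over repeats, the model refit on the full cohort at that lambda,
    and genes with nonzero coefficients returned.
    """
    y = cohort.label.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("label has a single class; LASSO undefined")
    x = _standardize(cohort.expression.to_numpy())
    n = len(y)

    # lambda_max: smallest penalty that zeroes every coefficient
    lam_max = np.abs(x.T @ (y - y.mean())).max() / n
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambdas)
    cs = 1.0 / (lambdas * n)

    chosen_log_lam = []
    path_rows = []
    for rep in range(n_repeats):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        dev = np.zeros(n_lambdas)
        for train, test in cv.split(x, y):
            for i, c in enumerate(cs):
                clf = LogisticRegression(
                    l1_ratio=1.0, C=c, solver="liblinear", max_iter=200
                )
                clf.fit(x[train], y[train])
                p = np.clip(clf.predict_proba(x[test])[:, 1], 1e-12, 1 - 1e-12)
                dev[i] += -2 * np.sum(
                    y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)
                )
        i_min = int(np.argmin(dev))
        chosen_log_lam.append(np.log10(lambdas[i_min]))
        for i, lam in enumerate(lambdas):
            path_rows.append(
                {"repeat": rep, "lambda": lam, "cv_deviance": dev[i] / n}
            )

    lam_min = 10 ** float(np.mean(chosen_log_lam))
    final = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam_min * n), solver="liblinear", max_iter=500
    )
    final.fit(x, y)
    coef = final.coef_.ravel()
    genes = [g for g, c in zip(cohort.genes, coef) if c != 0.0]
    table = pd.DataFrame(path_rows)
    table.attrs["lambda_min"] = lam_min
    return genes, table


# ----------------------------------------------------- univariate Cox ----


def cox_fit_single(
    x: np.ndarray, time: np.ndarray, event: np.ndarray,
    tol: float = 1e-8, max_iter: int = 50,
) -> tuple[float, float, float]:
    """Newton-Raphson fit of a one-covariate Cox model, Breslow ties.

    Returns (beta, se, wald_p). The covariate is used as passed (standardize
    upstream if desired).
    """
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    x, time, event = x[order], time[order], event[order]
    n = len(x)
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        # Breslow: every event at time t uses the full risk set {j: t_j >= t}
        last = np.searchsorted(-time, -time, side="right") - 1
        e = event == 1
        s0e, s1e, s2e = s0[last][e], s1[last][e], s2[last][e]
        grad = float(np.sum(x[e] - s1e / s0e))
        hess = float(-np.sum(s2e / s0e - (s1e / s0e) ** 2))
        if hess == 0:
            raise RuntimeError("singular Hessian in Cox fit")
        step = grad / hess
        beta -= step
        if abs(grad) < tol:
            break
    else:
        raise RuntimeError("Cox fit did not converge")
    se = float(np.sqrt(-1.0 / hess))
    p = float(2 * scipy.stats.norm.sf(abs(beta) / se))
    return beta, se, p


def select_unicox(
    cohort: CohortTable, p_max: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Per-gene univariate Cox on standardized expression; keep p < p_max."""
    time = cohort.time.to_numpy(dtype=float)
    event = cohort.event.to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events observed; Cox regression undefined")
    x = _standardize(cohort.expression.to_numpy())
    rows = []
    for j, gene in enumerate(cohort.genes):
        try:
            beta, se, p = cox_fit_single(x[:, j], time, event)
        except RuntimeError as exc:
            warnings.warn(f"Cox fit skipped for {gene}: {exc}")
            continue
        rows.append(
            {"gene": gene, "log_hr": beta, "hr": float(np.exp(beta)),
             "se": se, "p": p}
        )
    table = pd.DataFrame(rows, columns=["gene", "log_hr", "hr", "se", "p"])
    genes = table.loc[table["p"] < p_max, "gene"].tolist()
    return genes, table


# ----------------------------------------------- random forest + Boruta ----


def oob_permutation_importance(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> np.ndarray:
    """Breiman OOB permutation importance of a bootstrap CART ensemble.

    For each bootstrap tree, each feature the tree actually splits on is
    permuted on the tree's out-of-bag samples; the importance is the mean
    drop in OOB accuracy across trees (features a tree never uses
    contribute an exact zero for that tree).
    """
    rng = np.random.default_rng(seed)
    n, p = x.shape
    total = np.zeros(p)
    counts = np.zeros(p)
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), np.unique(idx))
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(x[idx], y[idx])
        x_oob, y_oob = x[oob], y[oob]
        base = float(np.mean(tree.predict(x_oob) == y_oob))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        counts += 1
        for j in used:
            xp = x_oob.copy()
            xp[:, j] = xp[rng.permutation(oob.size), j]
            perm = float(np.mean(tree.predict(xp) == y_oob))
            total[j] += base - perm
    counts[counts == 0] = 1
    return total / counts


def select_rf(
    cohort: CohortTable,
    n_top: int = 20,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Top genes by random-forest OOB permutation importance."""
    x = cohort.expression.to_numpy()
    y = cohort.label.to_numpy()
    imp = oob_permutation_importance(x, y, n_trees=n_trees, seed=seed)
    table = pd.DataFrame({"gene": cohort.genes, "importance": imp}).sort_values(
        "importance", ascending=False, kind="stable"
    )
    return table["gene"].head(n_top).tolist(), table.reset_index(drop=True)


def select_boruta(
    cohort: CohortTable,
    max_iter: int = 100,
    alpha: float = 0.01,
    n_trees: int = 150,
    min_iter: int = 5,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """All-relevant feature selection against shuffled shadow features.

    Each iteration appends an independently shuffled copy of every feature,
    fits the bootstrap forest, and scores a "hit" for each real feature
    whose importance exceeds the best shadow importance. Undecided features
    are tested two-sided binomial (hits vs 0.5) with Bonferroni correction;
    features are confirmed/rejected at p < alpha, the rest stay tentative.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10 for the binomial test to decide")
    rng = np.random.default_rng(seed)
    x = cohort.expression.to_numpy()
    y = cohort.label.to_numpy()
    n, p = x.shape
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    decision = np.array(["tentative"] * p, dtype=object)

    for it in range(1, max_iter + 1):
        undecided = decision == "tentative"
        if not undecided.any():
            break
        shadow = x.copy()
        for j in range(p):
            shadow[:, j] = shadow[rng.permutation(n), j]
        imp = oob_permutation_importance(
            np.hstack([x, shadow]), y, n_trees=n_trees,
            seed=int(rng.integers(2**31)),
        )
        real_imp, shadow_imp = imp[:p], imp[p:]
        thresh = shadow_imp.max()
        hits[undecided] += (real_imp[undecided] > thresh).astype(int)
        trials[undecided] += 1

        if it >= min_iter:
            idx = np.flatnonzero(undecided)
            n_tests = len(idx)
            for j in idx:
                res = scipy.stats.binomtest(int(hits[j]), int(trials[j]), 0.5)
                if res.pvalue * n_tests < alpha:
                    decision[j] = (
                        "confirmed" if hits[j] > trials[j] / 2 else "rejected"
                    )

    table = pd.DataFrame(
        {
            "gene": cohort.genes,
            "hits": hits,
            "trials": trials,
            "decision": decision,
        }
    )
    confirmed = table.loc[table["decision"] == "confirmed", "gene"].tolist()
    return confirmed, table


# -------------------------------------------------------------- XGBoost ----


def select_xgb(
    cohort: CohortTable,
    n_top: int | None = None,
    n_rounds: int = 200,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Gradient-boosted-tree gain ranking; select by the mean-gain rule.

    Features are ranked by total gain; by default genes whose gain exceeds
    the mean gain over all candidates are selected, or the top ``n_top``
    when given.
    """
    from xgboost import XGBClassifier

    x = cohort.expression.to_numpy()
    y = cohort.label.to_numpy()
    clf = XGBClassifier(
        n_estimators=n_rounds,
        random_state=seed,
        verbosity=0,
        eval_metric="logloss",
    )
    clf.fit(x, y)
    raw = clf.get_booster().get_score(importance_type="total_gain")
    gain = np.zeros(len(cohort.genes))
    for key, val in raw.items():
        gain[int(key[1:])] = val  # keys are f0, f1, ...
    table = pd.DataFrame({"gene": cohort.genes, "gain": gain}).sort_values(
        "gain", ascending=False, kind="stable"
    )
    if n_top is not None:
        genes = table["gene"].head(n_top).tolist()
    else:
        genes = table.loc[table["gain"] > gain.mean(), "gene"].tolist()
    return genes, table.reset_index(drop=True)


# --------------------------------------------------------- intersection ----


def intersect_selections(selections: dict[str, list[str]]) -> SelectionReport:
    """Strict intersection across all algorithm lists, plus diagnostics.

    The report also carries every pairwise and leave-one-out intersection,
    useful when one algorithm is the bottleneck.
    """
    names = list(selections)
    if not names:
        raise ValueError("no selections supplied")
    inter = list(selections[names[0]])
    for name in names[1:]:
        inter = [g for g in inter if g in set(selections[name])]
    report = SelectionReport(selections=dict(selections), intersection=inter)
    for r in (2, len(names) - 1):
        if r < 2 or r >= len(names) + 1:
            continue
        for combo in combinations(names, r):
            sub = list(selections[combo[0]])
            for name in combo[1:]:
                sub = [g for g in sub if g in set(selections[name])]
            report.subset_intersections["&".join(combo)] = sub
    assert all(
        set(report.intersection) <= set(v) for v in selections.values()
    ), "intersection must be a subset of every algorithm list"
    return report


def run_feature_selection(
    cohort: CohortTable,
    candidate_genes: list[str] | None = None,
    seed: int = 0,
    lasso_repeats: int = 10,
    rf_trees: int = 500,
    boruta_trees: int = 150,
) -> SelectionReport:
    """Run all five selectors on (optionally candidate-restricted) cohort."""
    if candidate_genes is not None:
        cohort = cohort.restrict(candidate_genes)
    report_sel: dict[str, list[str]] = {}
    diags: dict[str, object] = {}
    report_sel["lasso"], diags["lasso"] = select_lasso(
        cohort, n_repeats=lasso_repeats, seed=seed
    )
    report_sel["unicox"], diags["unicox"] = select_unicox(cohort)
    report_sel["rf"], diags["rf"] = select_rf(cohort, n_trees=rf_trees, seed=seed)
    report_sel["boruta"], diags["boruta"] = select_boruta(
        cohort, n_trees=boruta_trees, seed=seed
    )
    report_sel["xgb"], diags["xgb"] = select_xgb(cohort, seed=seed)
    report = intersect_selections(report_sel)
    report.diagnostics = diags
    return report
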