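"""Survival workflow: stratified split, preprocessing, elastic-net Cox with
nested cross-validated frequency-based selection, risk stratification and
Kaplan-Meier / logrank / concordance evaluation.

The elastic-net Cox fits minimize

    -(1/n) log PL(beta)  +  alpha * ( r ||beta||_1 + (1-r)/2 ||beta||_2^2 )

with Breslow tie handling; the heavy lifting is delegated to scikit-survival's
coordinate-descent path solver, with covariates standardized internally for
the penalty and coefficients mapped back to the input scale.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "ENCoxConfig",
    "SelectionResult",
    "split_train_test",
    "preprocess",
    "fit_encox",
    "nested_select",
    "evaluate_selection",
    "risk_score",
    "mean_split_groups",
    "kaplan_meier",
    "logrank",
    "chi2_upper_p",
    "concordance_index",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# estimators and tests
# ---------------------------------------------------------------------------

def chi2_upper_p(chi2: float, df: int = 1) -> float:
    """Upper-tail probability of a chi-square statistic."""
    if chi2 < 0:
        raise ValueError(f"chi2 must be >= 0, got {chi2}")
    return float(stats.chi2.sf(chi2, df))


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimator; returns (event times, S(t)) with S right-continuous."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = int(np.sum(time >= t))
        deaths = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return uniq, np.asarray(surv)


def logrank(
    time_a: np.ndarray, event_a: np.ndarray, time_b: np.ndarray, event_b: np.ndarray
) -> tuple[float, float]:
    """Two-group logrank test: (chi-square statistic, upper-tail p, 1 df).

    Zero hypergeometric variance (no informative event times) yields p = 1.
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("no events in either group")

    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    group = np.concatenate([np.zeros(time_a.size), np.ones(time_b.size)])

    o_a = 0.0
    e_a = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & (group == 0)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & (group == 0)).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n - d) * n_a * (n - n_a) / (n**2 * (n - 1))
    if var == 0:
        log.warning("logrank: zero variance; returning chi2=0, p=1")
        return 0.0, 1.0
    chi2 = (o_a - e_a) ** 2 / var
    return float(chi2), chi2_upper_p(chi2)


def concordance_index(time: np.ndarray, event: np.ndarray, scores: np.ndarray) -> float:
    """Harrell's C over censoring-comparable pairs; score ties count 0.5.

    A pair is comparable when the earlier subject had the event, or the times
    are tied with exactly one event (the censored subject outlived the other).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n = time.size
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] or (time[i] == time[j] and event[j] == 0):
                comparable += 1
                if scores[i] > scores[j]:
                    concordant += 1.0
                elif scores[i] == scores[j]:
                    concordant += 0.5
    if comparable == 0:
        raise ValueError("no comparable pairs under censoring")
    return concordant / comparable


# ---------------------------------------------------------------------------
# split & preprocessing
# ---------------------------------------------------------------------------

def split_train_test(
    data: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    event_col: str = "one_year_dead",
    strat_cols: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split on the 1-year event jointly with categoricals.

    Falls back to event-only stratification (then to none) when strata are too
    small to split.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 subjects to split")
    labels = data[event_col].astype(str)
    for col in strat_cols:
        labels = labels + "|" + data[col].astype(str)
    for attempt, strat in enumerate((labels, data[event_col], None)):
        try:
            train, test = train_test_split(
                data, test_size=test_fraction, random_state=seed, stratify=strat
            )
            if attempt > 0:
                log.warning("split: fell back to %s stratification",
                            "event-only" if attempt == 1 else "no")
            return train.copy(), test.copy()
        except ValueError:
            continue
    raise RuntimeError("unreachable")  # pragma: no cover


def preprocess(
    train: pd.DataFrame,
    test: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max normalize continuous columns (train-fitted) and one-hot encode
    categoricals with the train-defined category set.

    Test values outside the train range extrapolate outside [0, 1] (no
    clipping); unseen test categories map to all-zero indicator vectors.
    """
    out_train = pd.DataFrame(index=train.index)
    out_test = pd.DataFrame(index=test.index)
    for col in continuous:
        lo = float(train[col].min())
        hi = float(train[col].max())
        if hi == lo:
            log.warning("preprocess: constant column %r mapped to 0", col)
            out_train[col] = 0.0
            out_test[col] = 0.0
        else:
            out_train[col] = (train[col].astype(float) - lo) / (hi - lo)
            out_test[col] = (test[col].astype(float) - lo) / (hi - lo)
    for col in categorical:
        levels = sorted(train[col].astype(str).unique())
        unseen = set(test[col].astype(str).unique()) - set(levels)
        if unseen:
            log.warning("preprocess: unseen categories %s in column %r", sorted(unseen), col)
        for lev in levels:
            out_train[f"{col}_{lev}"] = (train[col].astype(str) == lev).astype(float)
            out_test[f"{col}_{lev}"] = (test[col].astype(str) == lev).astype(float)
    return out_train, out_test


# ---------------------------------------------------------------------------
# elastic-net Cox
# ---------------------------------------------------------------------------

def _surv_y(time: np.ndarray, event: np.ndarray):
    return Surv.from_arrays(event=np.asarray(event).astype(bool), time=np.asarray(time, float))


def fit_encox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    l1_ratio: float,
    alpha: float,
    standardize: bool = True,
    max_iter: int = 100000,
    tol: float = 1e-7,
) -> np.ndarray:
    """Elastic-net penalized Cox fit at a single (l1_ratio, alpha).

    ``alpha == 0`` falls back to the unpenalized Breslow fit; ``l1_ratio == 0``
    uses the equivalent ridge objective.  Coefficients are returned on the
    input covariate scale.
    """
    X = np.asarray(X, dtype=float)
    if not (0 <= l1_ratio <= 1):
        raise ValueError(f"l1_ratio must be in [0, 1], got {l1_ratio}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if int(np.asarray(event).sum()) < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    y = _surv_y(time, event)
    n = X.shape[0]

    if alpha == 0:
        model = CoxPHSurvivalAnalysis(alpha=1e-12, ties="breslow", n_iter=200)
        model.fit(X, y)
        return np.asarray(model.coef_, dtype=float)
    if l1_ratio == 0:
        # coxnet requires l1_ratio > 0; the pure-ridge objective maps onto the
        # Breslow Newton solver with penalty n * alpha
        model = CoxPHSurvivalAnalysis(alpha=n * alpha, ties="breslow", n_iter=200)
        model.fit(X, y)
        return np.asarray(model.coef_, dtype=float)

    scale = X.std(axis=0, ddof=0) if standardize else np.ones(X.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    Xs = X / scale
    model = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, alphas=[alpha], max_iter=max_iter, tol=tol, normalize=False
    )
    try:
        model.fit(Xs, y)
    except Exception as exc:
        raise RuntimeError(
            f"elastic-net Cox failed to converge at l1_ratio={l1_ratio}, alpha={alpha}: {exc}"
        ) from exc
    return np.asarray(model.coef_[:, 0], dtype=float) / scale


@dataclass
class ENCoxConfig:
    """Hyperparameter grids and structure of the nested-CV selection workflow."""

    l1_ratio_grid: tuple[float, ...] = (0.1, 0.5, 0.9)
    alpha_min_ratio_grid: tuple[float, ...] = (0.01,)
    n_alphas: int = 20
    max_iter: int = 100000
    tol: float = 1e-7
    outer_folds: int = 5
    inner_folds: int = 5
    inner_repeats: int = 10
    n_select: int = 7
    ridge_final: float = 1e-6
    refit_winner: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 <= r <= 1 for r in self.l1_ratio_grid):
            raise ValueError("l1_ratio values must be in [0, 1]")
        if not all(0 < a < 1 for a in self.alpha_min_ratio_grid):
            raise ValueError("alpha_min_ratio values must be in (0, 1)")
        if self.n_select < 1 or self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("invalid workflow structure")


@dataclass
class SelectionResult:
    """Winner of the nested-CV selection: the 7-feature model plus provenance."""

    selected: list[str]
    final_coefficients: dict[str, float]
    frequencies: dict[str, int]
    outer_scores: list[float]
    winner_fold: int
    fold_details: list[dict] = field(default_factory=list)
    test_concordance: float | None = None


def _rank_by_frequency(
    freq: Counter, coef_abs: dict[str, float], n_select: int
) -> list[str]:
    """Top-``n_select`` features by frequency; ties broken by larger mean
    absolute coefficient, then by name."""
    ordered = sorted(
        freq,
        key=lambda f: (-freq[f], -coef_abs.get(f, 0.0), f),
    )
    return ordered[:n_select]


def _cox_with_ridge(X: np.ndarray, y, ridge: float) -> np.ndarray:
    model = CoxPHSurvivalAnalysis(alpha=max(ridge, 1e-12), ties="breslow", n_iter=200)
    model.fit(X, y)
    return np.asarray(model.coef_, dtype=float)


def nested_select(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    config: ENCoxConfig,
) -> SelectionResult:
    """Nested cross-validated elastic-net Cox feature selection.

    Outer loop: stratified (on event) K-fold.  Per outer-train: repeated inner
    K-fold grid search over (l1_ratio, alpha_min_ratio, alpha along the path);
    each repeat refits at its best combination and records the nonzero
    features ranked by absolute coefficient.  The ``n_select`` most frequent
    features form that fold's model (lightly ridged Cox on the outer-train),
    scored by concordance on the outer-test.  The best-scoring fold's model is
    the winner, carried forward unrefit (unless ``refit_winner``).
    """
    X = X.copy()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    y_all = _surv_y(time, event)

    outer = StratifiedKFold(n_splits=config.outer_folds, shuffle=True, random_state=config.seed)
    fold_details: list[dict] = []
    outer_scores: list[float] = []
    fold_models: list[tuple[list[str], dict[str, float], Counter]] = []

    for fold_idx, (tr, te) in enumerate(outer.split(Xv, event)):
        X_tr, X_te = Xv[tr], Xv[te]
        t_tr, t_te = time[tr], time[te]
        e_tr, e_te = event[tr], event[te]
        freq: Counter = Counter()
        coef_abs_total: dict[str, float] = defaultdict(float)

        n_ok = 0
        for rep in range(config.inner_repeats):
            rep_seed = config.seed * 10007 + fold_idx * 101 + rep
            best = _inner_grid_search(X_tr, t_tr, e_tr, config, rep_seed)
            if best is None:
                continue
            r, alpha = best
            try:
                coefs = fit_encox(
                    X_tr, t_tr, e_tr, r, alpha, max_iter=config.max_iter, tol=config.tol
                )
            except RuntimeError:
                continue
            n_ok += 1
            nz = np.flatnonzero(coefs)
            ranked = sorted(nz, key=lambda k: -abs(coefs[k]))
            for k in ranked:
                freq[feature_names[k]] += 1
                coef_abs_total[feature_names[k]] += abs(coefs[k])
        if n_ok == 0:
            raise RuntimeError(
                f"outer fold {fold_idx}: no inner repetition produced a usable fit"
            )
        coef_abs_mean = {f: v / max(freq[f], 1) for f, v in coef_abs_total.items()}
        available = len(freq)
        if available == 0:
            # every repeat converged to the null model: rank by a light ridge fit
            log.warning(
                "outer fold %d: no feature ever nonzero; ranking by ridge coefficients",
                fold_idx,
            )
            ridge_coefs = _cox_with_ridge(X_tr, _surv_y(t_tr, e_tr), 1.0)
            order = np.argsort(-np.abs(ridge_coefs))[: config.n_select]
            selected = [feature_names[k] for k in order]
        else:
            if available < config.n_select:
                log.warning(
                    "outer fold %d: only %d features ever nonzero (< %d); selecting all",
                    fold_idx, available, config.n_select,
                )
            selected = _rank_by_frequency(freq, coef_abs_mean, min(config.n_select, available))

        idx = [feature_names.index(f) for f in selected]
        coefs7 = _cox_with_ridge(X_tr[:, idx], _surv_y(t_tr, e_tr), config.ridge_final)
        scores_te = X_te[:, idx] @ coefs7
        ci = concordance_index(t_te, e_te, scores_te)
        outer_scores.append(float(ci))
        fold_models.append((selected, dict(zip(selected, coefs7.tolist())), freq))
        fold_details.append(
            {
                "fold": fold_idx,
                "selected": selected,
                "outer_concordance": float(ci),
                "frequencies": dict(freq),
            }
        )

    winner = int(np.argmax(outer_scores))
    selected, coef_map, freq = fold_models[winner]
    if config.refit_winner:
        idx = [feature_names.index(f) for f in selected]
        coefs = _cox_with_ridge(Xv[:, idx], y_all, config.ridge_final)
        coef_map = dict(zip(selected, coefs.tolist()))
    return SelectionResult(
        selected=list(selected),
        final_coefficients=coef_map,
        frequencies=dict(freq),
        outer_scores=outer_scores,
        winner_fold=winner,
        fold_details=fold_details,
    )


def _inner_grid_search(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, config: ENCoxConfig, seed: int
) -> tuple[float, float] | None:
    """One inner repetition: CV grid search over (l1_ratio, alpha_min_ratio,
    alpha path); returns the best (l1_ratio, alpha) or None if nothing fit."""
    y = _surv_y(time, event)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = X / scale
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    try:
        splits = list(inner.split(X, event))
    except ValueError:
        return None

    best_score = -np.inf
    best: tuple[float, float] | None = None
    for r in config.l1_ratio_grid:
        r_eff = max(r, 1e-2)  # coxnet path construction needs l1_ratio > 0
        for amr in config.alpha_min_ratio_grid:
            try:
                path_model = CoxnetSurvivalAnalysis(
                    l1_ratio=r_eff, alpha_min_ratio=amr, n_alphas=config.n_alphas,
                    max_iter=config.max_iter, tol=config.tol,
                )
                path_model.fit(Xs, y)
                alphas = np.asarray(path_model.alphas_)
            except Exception:
                continue
            scores = np.zeros(alphas.size)
            counts = np.zeros(alphas.size)
            for tr, te in splits:
                if event[te].sum() == 0 or event[tr].sum() < 2:
                    continue
                try:
                    m = CoxnetSurvivalAnalysis(
                        l1_ratio=r_eff, alphas=alphas, max_iter=config.max_iter,
                        tol=config.tol,
                    )
                    m.fit(Xs[tr], y[tr])
                except Exception:
                    continue
                for ai, a in enumerate(alphas):
                    try:
                        pred = m.predict(Xs[te], alpha=a)
                        scores[ai] += concordance_index(time[te], event[te], pred)
                        counts[ai] += 1
                    except Exception:
                        continue
            valid = counts > 0
            if not valid.any():
                continue
            mean_scores = np.where(valid, scores / np.maximum(counts, 1), -np.inf)
            ai = int(np.argmax(mean_scores))
            if mean_scores[ai] > best_score:
                best_score = float(mean_scores[ai])
                best = (float(r), float(alphas[ai]))
    return best


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------

def risk_score(coefficients: dict[str, float], features: pd.DataFrame | pd.Series) -> np.ndarray:
    """Linear predictor ``sum beta_f x_f``; every model feature must be present."""
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    missing = [f for f in coefficients if f not in features.columns]
    if missing:
        raise KeyError(f"missing model features: {missing}")
    names = list(coefficients)
    beta = np.array([coefficients[f] for f in names])
    return features[names].to_numpy(dtype=float) @ beta


def evaluate_selection(
    result: SelectionResult, X_test: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> float:
    """Score the winning model once on the held-out test set (concordance)."""
    scores = risk_score(result.final_coefficients, X_test)
    ci = concordance_index(np.asarray(time, float), np.asarray(event, int), scores)
    result.test_concordance = float(ci)
    return float(ci)


def mean_split_groups(scores: np.ndarray) -> np.ndarray:
    """High/low risk labels by the arithmetic-mean threshold of the scores.

    Returns a boolean array, True = high risk (strictly above the mean; ties
    go to low risk).  Raises if either group would be empty.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 subjects to form risk groups")
    high = scores > scores.mean()
    if high.all() or not high.any():
        raise ValueError("mean split produced an empty risk group")
    return high
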