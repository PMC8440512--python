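"""Hierarchical regression, shadow-feature forest selection and evaluation.

Three analysis stages share this module:

* the confirmatory Bayesian linear mixed model of accuracy on jerk, jerk
  difference and the mental-state factor (with their three-way interaction
  and a maximal-style random structure), sampled with a conjugate Gibbs
  sampler (:mod:`animakin._gibbs`);
* Boruta-style feature selection: a random forest is fit on the real
  features plus permuted "shadow" copies, a feature scores a hit when its
  permutation importance exceeds the best shadow importance, and a binomial
  test over rounds classifies it confirmed / rejected / tentative;
* a final forest on the confirmed features, evaluated by a 70/30
  train/test split.

Mental-state dummy coding: the mental condition is the reference level, so
the ``nonmental`` dummy carries the mental-vs-non-mental contrast and plain
slopes are the mental-condition effects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from statsmodels.stats.outliers_influence import variance_inflation_factor

from ._gibbs import RandomTerm, gibbs_lmm
from .scoring import FeatureTable

__all__ = [
    "ModelSpec",
    "ParameterSummary",
    "ModelFit",
    "ImportanceDecision",
    "confirmatory_spec",
    "similarity_specs",
    "fit_hierarchical_model",
    "build_item_table",
    "boruta_select",
    "evaluate_final_forest",
    "fit_similarity_models",
    "vif_report",
]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one hierarchical regression.

    ``fixed_terms`` are column names or ':'-joined interactions of columns;
    an intercept is always included.  ``random_terms`` are
    ``(group_column, slope_term_or_None)`` pairs; ``None`` is a random
    intercept.  Coefficient priors are normal(0, prior_sd); the sampler runs
    ``chains`` chains of ``iterations`` iterations including ``warmup``
    warmup iterations.
    """

    outcome: str
    fixed_terms: tuple[str, ...]
    random_terms: tuple[tuple[str, str | None], ...]
    prior_sd: float = 10.0
    chains: int = 4
    iterations: int = 5000
    warmup: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2")


@dataclass(frozen=True)
class ParameterSummary:
    mean: float
    ci_lo: float
    ci_hi: float
    p_gt_zero: float
    rhat: float

    @property
    def p_lt_zero(self) -> float:
        return 1.0 - self.p_gt_zero


@dataclass(frozen=True)
class ModelFit:
    """Posterior summaries and diagnostics of one fitted model."""

    params: dict[str, ParameterSummary]
    sigma: ParameterSummary
    random_sds: dict[str, ParameterSummary]
    divergences: int
    converged: bool
    spec: ModelSpec

    def to_dict(self) -> dict:
        return {
            name: {
                "mean": p.mean,
                "ci_lo": p.ci_lo,
                "ci_hi": p.ci_hi,
                "p_gt_zero": p.p_gt_zero,
                "rhat": p.rhat,
            }
            for name, p in self.params.items()
        }


#: reference level is the mental condition; `nonmental` carries the contrast
CONFIRMATORY_TERMS = (
    "jerk",
    "jerk_diff",
    "nonmental",
    "jerk:jerk_diff",
    "jerk:nonmental",
    "jerk_diff:nonmental",
    "jerk:jerk_diff:nonmental",
)


def confirmatory_spec(seed: int | None = None, **overrides) -> ModelSpec:
    """The confirmatory accuracy model: jerk x jerk-difference x mental state.

    Random intercepts for subject and animation; random slopes for the
    jerk-by-mental-state interaction varying by animation and for jerk
    difference varying by subject.
    """
    kwargs = dict(
        outcome="accuracy",
        fixed_terms=CONFIRMATORY_TERMS,
        random_terms=(
            ("observer_id", None),
            ("animation_id", None),
            ("animation_id", "jerk"),
            ("animation_id", "jerk:nonmental"),
            ("observer_id", "jerk_diff"),
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return ModelSpec(**kwargs)


def similarity_specs(seed: int | None = None, **overrides) -> tuple[ModelSpec, ModelSpec]:
    """The two movement-similarity models (split to avoid collinear VIFs).

    Model 1: acceleration difference, rotation difference, mental state;
    model 2: rotation difference, jerk difference, mental state — each with
    the mental-state interactions and random intercepts for subject and
    animation.
    """

    def spec(a: str, b: str, offset: int) -> ModelSpec:
        kwargs = dict(
            outcome="accuracy",
            fixed_terms=(
                a,
                b,
                "nonmental",
                f"{a}:nonmental",
                f"{b}:nonmental",
            ),
            random_terms=(("observer_id", None), ("animation_id", None)),
            seed=None if seed is None else seed + offset,
        )
        kwargs.update(overrides)
        return ModelSpec(**kwargs)

    return (
        spec("acceleration_diff", "rotation_diff", 0),
        spec("rotation_diff", "jerk_diff", 1),
    )


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    cols = term.split(":")
    out = np.ones(len(df))
    for c in cols:
        if c == "nonmental":
            if "nonmental" in df.columns:
                out = out * df["nonmental"].to_numpy(dtype=float)
            else:
                out = out * (~df["is_mental"].to_numpy(dtype=bool)).astype(float)
        else:
            out = out * df[c].to_numpy(dtype=float)
    return out


def _design(df: pd.DataFrame, spec: ModelSpec):
    X = np.column_stack(
        [np.ones(len(df))] + [_term_column(df, t) for t in spec.fixed_terms]
    )
    names = ["intercept"] + list(spec.fixed_terms)
    terms = []
    for group_col, slope in spec.random_terms:
        codes, levels = pd.factorize(df[group_col])
        z = np.ones(len(df)) if slope is None else _term_column(df, slope)
        label = f"{slope or '1'}|{group_col}"
        terms.append(
            RandomTerm(
                name=label, group_codes=codes, z=z, n_levels=len(levels)
            )
        )
    return X, names, terms


def _summarize(draws: np.ndarray) -> ParameterSummary:
    """Posterior summary from (chains, draws) samples."""
    flat = draws.reshape(-1)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    return ParameterSummary(
        mean=float(flat.mean()),
        ci_lo=float(lo),
        ci_hi=float(hi),
        p_gt_zero=float(np.mean(flat > 0)),
        rhat=float(az.rhat(az.convert_to_dataset(draws))["x"]),
    )


def fit_hierarchical_model(table: FeatureTable, spec: ModelSpec) -> ModelFit:
    """Fit a Bayesian LMM by Gibbs sampling and summarize the posterior.

    Predictors are expected to be preprocessed (z-scored) already.  A fit
    with any split-R-hat above 1.05 is flagged ``converged=False`` rather
    than raising; the Gibbs sampler has no divergent transitions, so the
    divergence count is structurally zero.
    """
    df = table.data
    y = df[spec.outcome].to_numpy(dtype=float)
    X, names, terms = _design(df, spec)
    res = gibbs_lmm(
        y,
        X,
        terms,
        prior_sd=spec.prior_sd,
        chains=spec.chains,
        iterations=spec.iterations,
        warmup=spec.warmup,
        seed=spec.seed,
    )
    params = {
        name: _summarize(res.beta[:, :, j]) for j, name in enumerate(names)
    }
    sigma = _summarize(np.sqrt(res.sigma2))
    random_sds = {name: _summarize(np.sqrt(d)) for name, d in res.tau2.items()}
    rhats = [p.rhat for p in params.values()]
    return ModelFit(
        params=params,
        sigma=sigma,
        random_sds=random_sds,
        divergences=0,
        converged=bool(np.all(np.array(rhats) <= 1.05)),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Items-based aggregation and forest analyses

_DIFF_COLUMNS = ("jerk_diff", "acceleration_diff", "rotation_diff")


def build_item_table(table: FeatureTable) -> FeatureTable:
    """Average trial rows per animation (item); drop observer-relative columns.

    Difference scores depend on the observer-animation pairing, not the item
    alone, so they are removed.
    """
    df = table.data
    drop = [c for c in _DIFF_COLUMNS if c in df.columns] + ["observer_id"]
    keep = df.drop(columns=[c for c in drop if c in df.columns])
    numeric = keep.select_dtypes(include=[np.number, bool]).columns.tolist()
    grouped = keep.groupby("animation_id", sort=True)
    agg = grouped[numeric].mean(numeric_only=False)
    if "word" in keep.columns:
        agg["word"] = grouped["word"].first()
    if "is_mental" in df.columns:
        agg["is_mental"] = grouped["is_mental"].first()
    return FeatureTable(agg.reset_index())


@dataclass(frozen=True)
class ImportanceDecision:
    feature: str
    mean_importance: float
    decision: str  # confirmed | rejected | tentative
    hits: int
    rounds: int
    shadow_max: float
    shadow_mean: float
    shadow_min: float

    def __post_init__(self) -> None:
        if self.decision not in ("confirmed", "rejected", "tentative"):
            raise ValueError(f"invalid decision {self.decision!r}")


def _feature_seed(seed: int, round_no: int, name: str) -> int:
    # stable per-feature stream: decisions do not depend on column order
    return (zlib.crc32(f"{seed}:{round_no}:{name}".encode()) & 0x7FFFFFFF)


def boruta_select(
    item_table: FeatureTable,
    features: list[str],
    outcome: str = "accuracy",
    n_trees: int = 500,
    mtry: int = 10,
    max_rounds: int = 100,
    p_threshold: float = 0.01,
    n_permutation_repeats: int = 5,
    seed: int | None = None,
) -> list[ImportanceDecision]:
    """Shadow-feature (Boruta-style) selection with a random-forest regressor.

    Each round appends a permuted shadow copy of every feature, fits a
    forest (``n_trees`` trees, ``mtry`` candidate variables per split) and
    computes permutation importances.  A real feature scores a hit when its
    importance exceeds the maximal shadow importance.  After each round a
    two-sided binomial test of the hit count against chance (0.5) classifies
    features as confirmed (significantly more hits) or rejected
    (significantly fewer); undecided features are tentative after
    ``max_rounds``.  Shadow features can never be confirmed: they only form
    the null reference.
    """
    df = item_table.data
    y = df[outcome].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("outcome is constant; nothing to select on")
    if len(features) < 2:
        raise ValueError("need at least 2 candidate features")
    order = sorted(features)
    X = df[order].to_numpy(dtype=float)
    n, p = X.shape
    base_seed = 0 if seed is None else int(seed)

    hits = {f: 0 for f in order}
    importances: dict[str, list[float]] = {f: [] for f in order}
    decided: dict[str, str] = {}
    shadow_stats: list[tuple[float, float, float]] = []

    rounds_run = 0
    for r in range(max_rounds):
        rounds_run = r + 1
        shadows = np.column_stack(
            [
                np.random.default_rng(_feature_seed(base_seed, r, f)).permutation(
                    X[:, j]
                )
                for j, f in enumerate(order)
            ]
        )
        design = np.hstack([X, shadows])
        forest_rng = _feature_seed(base_seed, r, "__forest__")
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=min(mtry, design.shape[1]),
            random_state=forest_rng,
            n_jobs=1,
        ).fit(design, y)
        imp = permutation_importance(
            forest,
            design,
            y,
            n_repeats=n_permutation_repeats,
            random_state=_feature_seed(base_seed, r, "__perm__"),
            n_jobs=1,
        ).importances_mean
        real_imp, shadow_imp = imp[:p], imp[p:]
        shadow_stats.append(
            (float(shadow_imp.max()), float(shadow_imp.mean()), float(shadow_imp.min()))
        )
        threshold = shadow_imp.max()
        for j, f in enumerate(order):
            importances[f].append(float(real_imp[j]))
            if f in decided:
                continue
            if real_imp[j] > threshold:
                hits[f] += 1
            test = stats.binomtest(hits[f], r + 1, 0.5)
            if test.pvalue < p_threshold:
                decided[f] = "confirmed" if hits[f] > (r + 1) / 2 else "rejected"
        if len(decided) == len(order):
            break

    shadow_max = float(np.mean([s[0] for s in shadow_stats]))
    shadow_mean = float(np.mean([s[1] for s in shadow_stats]))
    shadow_min = float(np.mean([s[2] for s in shadow_stats]))
    out = []
    for f in features:  # report in caller's order
        out.append(
            ImportanceDecision(
                feature=f,
                mean_importance=float(np.mean(importances[f])),
                decision=decided.get(f, "tentative"),
                hits=hits[f],
                rounds=rounds_run,
                shadow_max=shadow_max,
                shadow_mean=shadow_mean,
                shadow_min=shadow_min,
            )
        )
    return out


def evaluate_final_forest(
    item_table: FeatureTable,
    confirmed_features: list[str],
    outcome: str = "accuracy",
    split: float = 0.70,
    n_trees: int = 500,
    mtry: int = 10,
    seed: int | None = None,
) -> dict:
    """Train a forest on ``split`` of the items and score the held-out rest.

    Returns ``{"r_squared", "p_value", "n_train", "n_test"}`` where
    ``r_squared`` is the coefficient of determination of the held-out
    predictions and ``p_value`` is from the regression of observed on
    predicted values.
    """
    if not confirmed_features:
        raise ValueError("confirmed_features must be non-empty")
    df = item_table.data
    X = df[list(confirmed_features)].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if len(y) < 10:
        raise ValueError("too few rows for a 70/30 evaluation")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed, shuffle=True
    )
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=min(mtry, X.shape[1]),
        random_state=seed,
        n_jobs=1,
    ).fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    r2 = float(r2_score(y_te, pred))
    if np.std(pred) == 0:
        p_value = 1.0
    else:
        p_value = float(stats.linregress(pred, y_te).pvalue)
    return {
        "r_squared": r2,
        "p_value": p_value,
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
    }


def vif_report(table: FeatureTable, columns: list[str]) -> dict[str, float]:
    """Variance inflation factors for a predictor set (intercept included)."""
    df = table.data
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in columns]
    )
    return {
        col: float(variance_inflation_factor(X, j + 1))
        for j, col in enumerate(columns)
    }


def fit_similarity_models(
    table: FeatureTable, seed: int | None = None, **spec_overrides
) -> tuple[ModelFit, ModelFit, dict[str, float]]:
    """Fit the two movement-similarity models and emit a VIF report.

    The full predictor set (acceleration, rotation and jerk differences) is
    screened for collinearity; the two models split the collinear pair
    (acceleration difference vs jerk difference) as the analysis design
    prescribes.
    """
    vifs = vif_report(table, ["acceleration_diff", "rotation_diff", "jerk_diff"])
    spec1, spec2 = similarity_specs(seed=seed, **spec_overrides)
    fit1 = fit_hierarchical_model(table, spec1)
    fit2 = fit_hierarchical_model(table, spec2)
    return fit1, fit2, vifs
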