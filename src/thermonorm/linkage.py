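"""Linking expression plasticity to the regulatory architecture.

Three analyses relate per-gene plasticity to five regulatory covariates
(number of distinct TFs, number of distinct microRNAs, 5′-UTR length,
3′-UTR length, first-intron length):

* a Gaussian GLM of the fourth-root-transformed SOC on the covariates, with
  backward AIC selection and a deviance-R² decomposition attributing
  explained variance to each retained term;
* two-class linear discriminant analysis (LDA) of the direction of change
  (or curvature), trained on a random 60 % of genes and scored on the
  held-out 40 %;
* a random forest on the same split, with permutation importances.

U- and bell-shaped genes are excluded throughout: for those classes the
change of expression is not a monotone function of temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = [
    "ARCHITECTURE_FEATURES",
    "SocModelResult",
    "LdaResult",
    "RfResult",
    "LinkageResult",
    "fit_soc_model",
    "lda_classify",
    "rf_classify",
    "link_architecture",
]

ARCHITECTURE_FEATURES = ("n_tfs", "n_mirnas", "utr5_len", "utr3_len", "intron1_len")
MONOTONE_CLASSES = ("increasing", "decreasing")


@dataclass
class SocModelResult:
    """Gaussian GLM of SOC^(1/4) on the regulatory covariates."""

    summary: pd.DataFrame  # index: term; columns: coefficient, p_value, r2_share
    r2_full: float
    n_genes: int
    aic: float
    selected_terms: list[str]

    def to_tsv(self, path: str | Path) -> None:
        self.summary.rename_axis("term").to_csv(path, sep="\t")


@dataclass
class LdaResult:
    class_means: pd.DataFrame  # feature means per class (full data set)
    coefficients: pd.Series  # discriminant direction, raw feature scale
    coefficients_standardized: pd.Series
    holdout_accuracy: float
    baseline_accuracy: float  # training-majority class frequency in holdout
    n_train: int
    n_test: int
    split_seed: int
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class RfResult:
    holdout_accuracy: float
    baseline_accuracy: float
    importances: pd.Series  # permutation importance on the holdout
    n_train: int
    n_test: int
    split_seed: int


@dataclass
class LinkageResult:
    soc_model: SocModelResult
    direction_lda: LdaResult
    direction_rf: RfResult
    curvature_lda: LdaResult | None
    curvature_rf: RfResult | None
    split_seed: int


def _complete_cases(profiles: pd.DataFrame, arch: pd.DataFrame) -> pd.DataFrame:
    merged = profiles.join(arch[list(ARCHITECTURE_FEATURES)], how="inner")
    merged = merged[merged["class_label"].isin(MONOTONE_CLASSES)]
    return merged.dropna(subset=list(ARCHITECTURE_FEATURES))


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(f"singular design; most collinear pair: {worst}")
    return sm.OLS(y, design).fit()


def fit_soc_model(
    profiles: pd.DataFrame,
    arch: pd.DataFrame,
    select_aic: bool = True,
) -> SocModelResult:
    """Regress SOC^(1/4) of monotone genes on the regulatory covariates.

    Backward AIC elimination runs over the five main effects; the
    TFs:microRNAs interaction is then added if it lowers the AIC (the only
    interaction considered). Each term's R² share is the full-model
    explained deviance minus that of the model with the term and its
    interactions removed.
    """
    data = _complete_cases(profiles, arch)
    if len(data) < 10:
        raise ValueError(f"only {len(data)} complete-case monotone genes; need >= 10")

    y = data["soc"].to_numpy(dtype=float) ** 0.25
    feats = data[list(ARCHITECTURE_FEATURES)].astype(float)

    terms = list(ARCHITECTURE_FEATURES)
    if select_aic:
        current = _ols(y, feats[terms])
        improved = True
        while improved and len(terms) > 1:
            improved = False
            candidates = []
            for t in terms:
                reduced = [u for u in terms if u != t]
                candidates.append((t, _ols(y, feats[reduced])))
            t_best, fit_best = min(candidates, key=lambda c: c[1].aic)
            if fit_best.aic < current.aic:
                terms.remove(t_best)
                current = fit_best
                improved = True

    X = feats[terms].copy()
    interaction = False
    if "n_tfs" in terms and "n_mirnas" in terms:
        X_int = X.copy()
        X_int["n_tfs:n_mirnas"] = X_int["n_tfs"] * X_int["n_mirnas"]
        fit_no_int = _ols(y, X)
        fit_int = _ols(y, X_int)
        if not select_aic or fit_int.aic < fit_no_int.aic:
            X, interaction = X_int, True

    fit = _ols(y, X)
    tss = ((y - y.mean()) ** 2).sum()

    def r2_of(cols: list[str]) -> float:
        if not cols:
            return 0.0
        return 1.0 - _ols(y, X[cols]).ssr / tss

    r2_full = 1.0 - fit.ssr / tss
    all_cols = list(X.columns)
    shares: dict[str, float] = {}
    for t in terms:
        without = [c for c in all_cols if c != t and t not in c.split(":")]
        shares[t] = r2_full - r2_of(without)
    if interaction:
        shares["n_tfs:n_mirnas"] = r2_full - r2_of([c for c in all_cols if ":" not in c])

    rows = [("const", fit.params["const"], fit.pvalues["const"], np.nan)]
    for c in all_cols:
        rows.append((c, fit.params[c], fit.pvalues[c], shares.get(c, np.nan)))
    summary = pd.DataFrame(
        rows, columns=["term", "coefficient", "p_value", "r2_share"]
    ).set_index("term")
    return SocModelResult(
        summary=summary,
        r2_full=float(r2_full),
        n_genes=int(len(data)),
        aic=float(fit.aic),
        selected_terms=all_cols,
    )


def _split(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Simple random (unstratified) disjoint, exhaustive train/test split."""
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    return order[:n_train], order[n_train:]


def _prepare_xy(labels: pd.Series, features: pd.DataFrame, min_per_class: int):
    common = labels.dropna().index.intersection(features.dropna().index)
    y = labels.loc[common].astype(str)
    X = features.loc[common, list(features.columns)].astype(float)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    if (counts < min_per_class).any():
        small = counts[counts < min_per_class].to_dict()
        raise ValueError(f"classes below {min_per_class} genes: {small}")
    return X, y


def lda_classify(
    labels: pd.Series,
    features: pd.DataFrame,
    train_fraction: float = 0.60,
    seed: int = 0,
    min_per_class: int = 20,
) -> LdaResult:
    """Two-class LDA of a plasticity component on the regulatory covariates.

    Priors are the training class proportions; accuracy is evaluated on the
    held-out fraction only. Zero-variance features (in the training split)
    are dropped with a warning. Coefficients are the discriminant direction
    on the raw feature scale and standardized by the training-set feature
    standard deviations.
    """
    X, y = _prepare_xy(labels, features, min_per_class)
    if y.nunique() != 2:
        raise ValueError(f"LDA here is two-class; got classes {sorted(y.unique())}")
    tr, te = _split(len(y), train_fraction, seed)
    X_tr, y_tr = X.iloc[tr], y.iloc[tr]
    X_te, y_te = X.iloc[te], y.iloc[te]

    sds = X_tr.std(ddof=1)
    dropped = list(sds.index[sds == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        X_tr = X_tr.drop(columns=dropped)
        X_te = X_te.drop(columns=dropped)
        sds = sds.drop(index=dropped)

    lda = LinearDiscriminantAnalysis()  # empirical training priors
    lda.fit(X_tr.to_numpy(), y_tr.to_numpy())
    acc = float((lda.predict(X_te.to_numpy()) == y_te.to_numpy()).mean())

    majority = y_tr.value_counts().idxmax()
    baseline = float((y_te == majority).mean())

    coef = pd.Series(lda.scalings_[:, 0], index=X_tr.columns, name="coefficient")
    coef_std = (coef * sds).rename("coefficient_standardized")
    class_means = X.groupby(y).mean()
    return LdaResult(
        class_means=class_means,
        coefficients=coef,
        coefficients_standardized=coef_std,
        holdout_accuracy=acc,
        baseline_accuracy=baseline,
        n_train=len(tr),
        n_test=len(te),
        split_seed=seed,
        dropped_features=dropped,
    )


def rf_classify(
    labels: pd.Series,
    features: pd.DataFrame,
    train_fraction: float = 0.60,
    n_trees: int = 500,
    seed: int = 0,
    min_per_class: int = 20,
    n_importance_repeats: int = 10,
) -> RfResult:
    """Random-forest classification on the same split design as the LDA."""
    X, y = _prepare_xy(labels, features, min_per_class)
    tr, te = _split(len(y), train_fraction, seed)
    X_tr, y_tr = X.iloc[tr], y.iloc[tr]
    X_te, y_te = X.iloc[te], y.iloc[te]

    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(X_tr.to_numpy(), y_tr.to_numpy())
    acc = float(rf.score(X_te.to_numpy(), y_te.to_numpy()))

    majority = y_tr.value_counts().idxmax()
    baseline = float((y_te == majority).mean())

    imp = permutation_importance(
        rf,
        X_te.to_numpy(),
        y_te.to_numpy(),
        n_repeats=n_importance_repeats,
        random_state=seed,
    )
    importances = pd.Series(imp.importances_mean, index=X.columns, name="permutation_importance")
    return RfResult(
        holdout_accuracy=acc,
        baseline_accuracy=baseline,
        importances=importances,
        n_train=len(tr),
        n_test=len(te),
        split_seed=seed,
    )


def link_architecture(
    profiles: pd.DataFrame,
    arch: pd.DataFrame,
    train_fraction: float = 0.60,
    seed: int = 0,
) -> LinkageResult:
    """Run all three linkage analyses on monotone, complete-case genes."""
    data = _complete_cases(profiles, arch)
    soc_model = fit_soc_model(profiles, arch)
    features = data[list(ARCHITECTURE_FEATURES)]

    direction = data["class_label"]
    dir_lda = lda_classify(direction, features, train_fraction, seed)
    dir_rf = rf_classify(direction, features, train_fraction, seed=seed)

    curvature = data["curvature"]
    try:
        curv_lda = lda_classify(curvature, features, train_fraction, seed)
        curv_rf = rf_classify(curvature, features, train_fraction, seed=seed)
    except ValueError:
        curv_lda = curv_rf = None  # e.g. one curvature class absent
    return LinkageResult(soc_model, dir_lda, dir_rf, curv_lda, curv_rf, seed)
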