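"""Logistic risk-score construction for pCR prediction.

Three linear scores are built the same way the study's models are defined:

* a clinical-factor score (CF-PM) over factors passing a p < 0.1 screen;
* a small-RNA score (SR-PM) built by ranking candidate features by their
  cross-validated univariate odds ratio and nesting the top 1..k features;
* a combined score (C-PM) over both predictor sets.

"Cross-validated five times with a learning-to-validation ratio of 8:2" is
implemented as stratified 5-fold CV (each fold is the 20 % validation
part); a repeated random 80/20-split mode is available since the wording
supports either.  Model selection maximizes mean CV AUC (ties favour fewer
features) and the selected model is refit on all data to yield the single
final equation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .selection import LabeledMatrix, compare_clinical

Z95 = 1.959963984540054


@dataclass
class ClinicalRecord:
    """One patient's covariates, pCR label and survival outcomes."""

    age: float
    sex: str  # "M" | "F"
    tumor_diameter: float  # mm
    cT: str  # "1-2" | "3-4"
    cN: str  # "0" | "1-3"
    cM: str  # "0" | "1(LYM)"
    endoscopic_cCR: bool
    overall_cCR: bool
    biopsy_positive: bool
    post_CEA: float  # ng/mL
    post_SCC: float  # ng/mL
    pct_delta_suvmax: float  # percent, in [0, 100]
    pcr_label: bool
    rfs_time: float = 0.0  # months from surgery
    rfs_event: bool = False
    os_time: float = 0.0
    os_event: bool = False

    def __post_init__(self):
        if not 0 <= self.pct_delta_suvmax <= 100:
            raise ValueError("pct_delta_suvmax must be in [0, 100]")
        if self.post_CEA <= 0 or self.post_SCC <= 0:
            raise ValueError("tumor markers must be > 0")
        if self.rfs_time < 0 or self.os_time < 0:
            raise ValueError("survival times must be >= 0")


#: Clinical factors screened for the CF-PM, name -> (attribute/derivation, kind).
CLINICAL_FACTORS: dict[str, tuple[str, str]] = {
    "age": ("age", "continuous"),
    "sex_male": ("sex", "categorical"),
    "tumor_diameter": ("tumor_diameter", "continuous"),
    "cT3-4": ("cT", "categorical"),
    "cN1-3": ("cN", "categorical"),
    "cM1(LYM)": ("cM", "categorical"),
    "endoscopic_cCR": ("endoscopic_cCR", "categorical"),
    "overall_cCR": ("overall_cCR", "categorical"),
    "biopsy_positive": ("biopsy_positive", "categorical"),
    "post_CEA": ("post_CEA", "continuous"),
    "post_SCC": ("post_SCC", "continuous"),
    "pct_delta_suvmax": ("pct_delta_suvmax", "continuous"),
}

#: Factors entering the design matrix as 0/1 indicators, by factor name.
_BINARY_POSITIVE = {
    "sex_male": ("sex", "M"),
    "cT3-4": ("cT", "3-4"),
    "cN1-3": ("cN", "1-3"),
    "cM1(LYM)": ("cM", "1(LYM)"),
}


def clinical_design(records: Sequence[ClinicalRecord], factors: Sequence[str]) -> pd.DataFrame:
    """0/1 or numeric design-matrix columns for the named clinical factors."""
    cols = {}
    for name in factors:
        attr, _kind = CLINICAL_FACTORS[name]
        if name in _BINARY_POSITIVE:
            attr, pos = _BINARY_POSITIVE[name]
            cols[name] = [1.0 if getattr(r, attr) == pos else 0.0 for r in records]
        elif isinstance(getattr(records[0], attr), bool):
            cols[name] = [1.0 if getattr(r, attr) else 0.0 for r in records]
        else:
            cols[name] = [float(getattr(r, attr)) for r in records]
    return pd.DataFrame(cols)


@dataclass
class ModelCoefficients:
    """Intercept plus named coefficients of a linear (log-odds) score."""

    intercept: float
    coefficients: dict[str, float]
    predictor_kinds: dict[str, str] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)  # includes "intercept"
    odds_ratios: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    separation: bool = False
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "predictor_kinds": self.predictor_kinds,
            "se": self.se,
            "odds_ratios": {k: list(v) for k, v in self.odds_ratios.items()},
            "p_values": self.p_values,
            "separation": self.separation,
            "converged": self.converged,
            "extras": self.extras,
        }


def linear_score(model: ModelCoefficients, inputs: Mapping[str, float]) -> float:
    """Evaluate the linear predictor (the "Score", not a probability)."""
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in inputs:
            raise KeyError(f"missing predictor {name!r}")
        total += coef * float(inputs[name])
    return float(total)


class SeparationError(RuntimeError):
    pass


def _firth_fit(X: np.ndarray, y: np.ndarray, maxiter: int = 200, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior score adjustment).

    Always yields finite coefficients, including under complete separation;
    used as the optional fallback when the ML fit separates.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(maxiter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p)
        XtW = X.T * w
        fisher = XtW @ X
        fisher_inv = np.linalg.pinv(fisher)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], fisher_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = fisher_inv @ score
        beta = beta + step
        if np.max(np.abs(score)) < tol:
            break
    cov = np.linalg.pinv(fisher)
    return beta, np.sqrt(np.diag(cov))


def fit_logistic(
    design: pd.DataFrame,
    outcome: Sequence[int],
    firth: bool = False,
    min_samples: int = 10,
) -> ModelCoefficients:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals.

    Constant predictor columns are dropped (an all-constant design yields
    the intercept-only model with intercept = logit(prevalence)).  Complete
    or quasi-separation is detected and flagged; with ``firth=True`` a
    Firth-penalized fit is returned instead of divergent ML coefficients.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {len(y)}")
    classes = np.unique(y)
    if set(classes) - {0.0, 1.0} or len(classes) < 2:
        raise ValueError("outcome must contain both classes coded 0/1")

    design = design.astype(float)
    kept = [c for c in design.columns if design[c].nunique() > 1]
    dropped = [c for c in design.columns if c not in kept]
    X = sm.add_constant(design[kept], has_constant="add")

    if not kept:
        prev = float(np.mean(y))
        return ModelCoefficients(
            intercept=float(logit(prev)),
            coefficients={},
            extras={"dropped_constant": dropped, "note": "intercept-only"},
        )

    separated = False
    params = bse = pvals = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            params, bse, pvals = res.params, res.bse, res.pvalues
            converged = bool(res.mle_retvals.get("converged", True))
            # quasi-separation shows up as runaway coefficients / zero SE
            if not converged or np.max(np.abs(params.to_numpy())) > 30:
                separated = True
        except Exception:
            separated = True

    if separated:
        if not firth:
            return ModelCoefficients(
                intercept=float("nan"),
                coefficients={c: float("nan") for c in kept},
                separation=True,
                converged=False,
                extras={"dropped_constant": dropped, "note": "separation detected; no coefficients returned"},
            )
        beta, se_vec = _firth_fit(X.to_numpy(), y)
        params = pd.Series(beta, index=X.columns)
        bse = pd.Series(se_vec, index=X.columns)
        z = params / bse.replace(0, np.nan)
        pvals = pd.Series(2 * (1 - _std_norm_cdf(np.abs(z.to_numpy()))), index=X.columns)

    ors = {
        c: (
            float(np.exp(params[c])),
            float(np.exp(params[c] - Z95 * bse[c])),
            float(np.exp(params[c] + Z95 * bse[c])),
        )
        for c in kept
    }
    return ModelCoefficients(
        intercept=float(params["const"]),
        coefficients={c: float(params[c]) for c in kept},
        se={"intercept": float(bse["const"]), **{c: float(bse[c]) for c in kept}},
        odds_ratios=ors,
        p_values={c: float(pvals[c]) for c in kept},
        separation=separated,
        converged=not separated,
        extras={"dropped_constant": dropped, "firth": separated and firth},
    )


def _std_norm_cdf(x):
    from scipy.stats import norm

    return norm.cdf(x)


def screen_clinical(
    records: Sequence[ClinicalRecord],
    alpha_enter: float = 0.1,
    factors: Sequence[str] | None = None,
) -> list[str]:
    """Clinical factors whose group-comparison p-value is below the entry
    threshold (default 0.1), in the canonical factor order."""
    labels = [r.pcr_label for r in records]
    if sum(labels) < 2 or sum(not l for l in labels) < 2:
        raise ValueError("need at least 2 patients per class")
    factors = list(factors) if factors is not None else list(CLINICAL_FACTORS)
    selected = []
    for name in factors:
        attr, kind = CLINICAL_FACTORS[name]
        values = [getattr(r, attr) for r in records]
        try:
            p = compare_clinical(values, labels, kind)
        except ValueError:
            continue  # degenerate factor (single level) cannot be screened
        if p < alpha_enter:
            selected.append(name)
    return selected


@dataclass
class CVConfig:
    n_folds: int = 5
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0
    mode: str = "kfold"  # "kfold" | "splits" (repeated random 80/20)

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("kfold", "splits"):
            raise ValueError("mode must be 'kfold' or 'splits'")


def _folds(y: np.ndarray, cv: CVConfig):
    if cv.mode == "kfold":
        splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=cv.n_folds, train_size=cv.train_fraction, random_state=cv.seed
        )
    return list(splitter.split(np.zeros_like(y), y))


#: Expression increment for odds-ratio ranking: ORs are per 100 normalized
#: units so features on different scales are comparable.
OR_RANK_UNIT = 100.0


def rank_features_by_cv_or(
    lm: LabeledMatrix,
    features: Sequence[str],
    cv: CVConfig | None = None,
    ascending: bool = False,
) -> list[tuple[str, float]]:
    """Rank candidate features by their mean cross-validated univariate OR.

    Per fold, a univariate logistic model of pCR on the feature (scaled to
    per-100-unit increments) is fit on the training part; features are
    ordered by the mean over folds of exp(coef), strongest first by default
    (``ascending=True`` gives the literal ascending order).  Ties break
    lexicographically.  Separated folds fall back to the Firth fit so the
    OR stays finite.
    """
    cv = cv or CVConfig()
    missing = set(features) - set(lm.matrix.feature_ids)
    if missing:
        raise ValueError(f"features not in matrix: {sorted(missing)}")
    y = (lm.labels.loc[lm.matrix.sample_ids] == "pCR").to_numpy(dtype=float)
    folds = _folds(y, cv)
    mean_or: dict[str, float] = {}
    for feat in features:
        x = lm.matrix.values[feat].to_numpy(dtype=float) / OR_RANK_UNIT
        ors = []
        for train, _test in folds:
            fit = fit_logistic(
                pd.DataFrame({feat: x[train]}), y[train], firth=True, min_samples=4
            )
            ors.append(fit.odds_ratios.get(feat, (1.0, np.nan, np.nan))[0])
        mean_or[feat] = float(np.mean(ors))
    ranked = sorted(mean_or.items(), key=lambda t: (t[1] if ascending else -t[1], t[0]))
    return ranked


@dataclass
class CVMetrics:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    auc: float
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class NestedModelEntry:
    k: int
    features: list[str]
    clinical_terms: list[str]
    coefficients: ModelCoefficients  # full-data refit
    cv_metrics: CVMetrics


@dataclass
class NestedModelsResult:
    entries: list[NestedModelEntry]
    best_k: int

    @property
    def best(self) -> NestedModelEntry:
        return next(e for e in self.entries if e.k == self.best_k)

    @property
    def final_coefficients(self) -> ModelCoefficients:
        return self.best.coefficients


def _cv_evaluate(X: pd.DataFrame, y: np.ndarray, cv: CVConfig, threshold: float = 0.5) -> CVMetrics:
    from .evaluation import classification_metrics, roc_auc

    accs, precs, recs, fs, aucs = [], [], [], [], []
    for train, test in _folds(y, cv):
        fit = fit_logistic(X.iloc[train], y[train], firth=True, min_samples=4)
        scores = np.array(
            [
                expit(linear_score(fit, X.iloc[i].to_dict()))
                for i in test
            ]
        )
        if len(np.unique(y[test])) < 2:
            continue  # fold carries no information for discrimination metrics
        rep = classification_metrics(scores, y[test], threshold)
        accs.append(rep.accuracy)
        precs.append(rep.precision)
        recs.append(rep.recall)
        fs.append(rep.f_measure)
        aucs.append(roc_auc(scores, y[test]).auc)
    return CVMetrics(
        accuracy=float(np.mean(accs)),
        precision=float(np.nanmean(precs)) if precs else float("nan"),
        recall=float(np.mean(recs)),
        f_measure=float(np.nanmean(fs)) if fs else float("nan"),
        auc=float(np.mean(aucs)),
        threshold=threshold,
    )


def build_nested_models(
    lm: LabeledMatrix,
    ranked_features: Sequence[str],
    clinical_design_df: pd.DataFrame | None = None,
    max_k: int = 3,
    cv: CVConfig | None = None,
) -> NestedModelsResult:
    """Fit nested models over the top-1..max_k ranked features (plus fixed
    clinical terms when given), report mean CV metrics per model, select
    the best by AUC (ties: fewer features) and refit it on all data."""
    if not ranked_features:
        raise ValueError("ranked_features must be non-empty")
    cv = cv or CVConfig()
    y = (lm.labels.loc[lm.matrix.sample_ids] == "pCR").to_numpy(dtype=float)
    entries: list[NestedModelEntry] = []
    clin_cols = []
    if clinical_design_df is not None:
        clinical_design_df = clinical_design_df.reset_index(drop=True)
        clin_cols = list(clinical_design_df.columns)
    for k in range(1, min(max_k, len(ranked_features)) + 1):
        feats = list(ranked_features[:k])
        X = lm.matrix.values[feats].reset_index(drop=True).astype(float)
        if clin_cols:
            X = pd.concat([clinical_design_df, X], axis=1)
        metrics = _cv_evaluate(X, y, cv)
        final = fit_logistic(X, y, firth=True)
        entries.append(
            NestedModelEntry(
                k=k,
                features=feats,
                clinical_terms=clin_cols,
                coefficients=final,
                cv_metrics=metrics,
            )
        )
    best = max(entries, key=lambda e: (round(e.cv_metrics.auc, 12), -e.k))
    return NestedModelsResult(entries=entries, best_k=best.k)
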