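"""Logistic models for predicting low-risk lesions and patients.

Five model families combine pre-biopsy clinical variables and radiomic
features (outcome: the lesion/patient is low risk by the combined
clinical-genomic criteria):

1. clinical only — age, PSA density, DRE (0 vs 1–2), PI-RADS (1–2 vs 3–5);
2. lesion radiomics;
3. lesion + NAPZ/NATZ radiomics;
4. clinical + lesion radiomics;
5. clinical + lesion + NAPZ/NATZ radiomics.

Radiomic pools are high-dimensional and highly correlated, so variables
are selected by the **adaptive LASSO**: an initial ridge-penalized
logistic fit provides per-variable weights ``w_j = 1 / |beta_j|^gamma``,
and a weighted L1 logistic path is tuned by stratified K-fold
cross-validated deviance.  Tumor volume (``HRS6``) is forced into every
radiomics model without undergoing selection; clinical variables in
models 4–5 likewise enter unpenalized.  The final model is an
unpenalized logistic refit on the selected + forced variables (with a
ridge-stabilized fallback when separation prevents convergence).

All model inputs are standardized (zero mean, unit variance on training
data) and the standardization parameters are stored and reapplied
verbatim at prediction time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from radiorisk.radiomics import HRS6_NAME, feature_names

logger = logging.getLogger(__name__)

#: engineered clinical inputs (dichotomizations applied by clinical_matrix)
CLINICAL_VARIABLES: tuple[str, ...] = ("age", "psad", "dre_pos", "pirads_high")

LABEL_COLUMN = "low_risk"


def clinical_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Engineer the four clinical model inputs from raw cohort columns.

    DRE is dichotomized 0 vs {1, 2} and PI-RADS 1–2 vs 3–5, following
    the pre-biopsy modeling convention; age and PSA density stay
    continuous.
    """
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"].astype(float)
    out["psad"] = df["psad"].astype(float)
    out["dre_pos"] = (df["dre"].astype(int) > 0).astype(float)
    out["pirads_high"] = (df["pirads"].astype(int) >= 3).astype(float)
    return out


@dataclass(frozen=True)
class SelectionParams:
    """Adaptive-LASSO settings.

    The penalty is chosen on a log-spaced path by stratified K-fold
    cross-validated deviance with the one-standard-error rule: the
    strongest penalty whose mean CV deviance is within one standard
    error of the optimum.  ``one_se=False`` takes the deviance minimum
    instead.
    """

    gamma: float = 1.0
    ridge_c: float = 1.0
    n_folds: int = 10
    n_penalties: int = 20
    penalty_range: tuple[float, float] = (-3.0, 1.0)  # log10(C) range
    one_se: bool = True


@dataclass(frozen=True)
class ModelSpec:
    """Which variable pool a model draws from.

    ``intensity_only`` restricts radiomic pools to the first-order
    (``int``) features, the easy-to-compute and highly reproducible
    subset.
    """

    model_id: int
    intensity_only: bool = False
    selection: SelectionParams = field(default_factory=SelectionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4, 5):
            raise ValueError(f"model_id must be 1..5, got {self.model_id}")

    def _radiomic_pool(self) -> list[str]:
        if self.model_id == 1:
            return []
        names = feature_names("L") if self.model_id in (2, 4) else feature_names()
        if self.intensity_only:
            names = [n for n in names if n.split("_")[2] == "int"]
        return names

    @property
    def penalized_pool(self) -> list[str]:
        """Radiomic variables that undergo adaptive-LASSO selection."""
        return self._radiomic_pool()

    @property
    def forced_variables(self) -> list[str]:
        """Variables included without selection (tumor volume, radiomics models)."""
        return [HRS6_NAME] if self.model_id != 1 else []

    @property
    def clinical_variables(self) -> list[str]:
        """Unpenalized clinical inputs (models 1, 4 and 5)."""
        return list(CLINICAL_VARIABLES) if self.model_id in (1, 4, 5) else []


@dataclass
class StandardizationParams:
    center: dict[str, float]
    scale: dict[str, float]
    medians: dict[str, float]
    dropped: list[str]


def standardize(
    X: pd.DataFrame, params: StandardizationParams | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Zero-mean unit-variance columns; refit or reapply stored parameters.

    On fitting, zero-variance columns are dropped (logged) and training
    medians stored for imputation of missing values; at prediction the
    stored parameters are reapplied verbatim.
    """
    X = X.astype(float)
    if params is None:
        if X.isna().all().any():
            bad = list(X.columns[X.isna().all()])
            raise ValueError(f"all-missing column(s): {bad}")
        medians = X.median()
        X = X.fillna(medians)
        sd = X.std(ddof=0)
        dropped = list(X.columns[sd == 0])
        if dropped:
            logger.warning("dropping %d zero-variance column(s): %s",
                           len(dropped), dropped[:8])
        keep = [c for c in X.columns if c not in dropped]
        X = X[keep]
        params = StandardizationParams(
            center=X.mean().to_dict(),
            scale=X.std(ddof=0).to_dict(),
            medians=medians.to_dict(),
            dropped=dropped,
        )
    keep = list(params.center)
    missing = [c for c in keep if c not in X.columns]
    if missing:
        raise KeyError(f"missing model variable(s): {missing}")
    X = X[keep].fillna(pd.Series(params.medians))
    out = (X - pd.Series(params.center)) / pd.Series(params.scale)
    return out, params


def adaptive_lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    params: SelectionParams | None = None,
    seed: int = 0,
) -> list[str]:
    """Two-stage adaptive-LASSO variable selection for logistic regression.

    Stage 1 fits a ridge-penalized logistic model; stage 2 runs a
    weighted L1 path (column *j* scaled by ``|beta_ridge_j|**gamma``)
    with the penalty chosen by stratified K-fold cross-validated
    deviance (one-SE rule by default).  Returns the names with nonzero
    selected coefficients.
    """
    params = params or SelectionParams()
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("adaptive_lasso_select requires both classes present in y")
    if X.shape[1] == 0:
        return []

    ridge = LogisticRegression(C=params.ridge_c, solver="lbfgs", max_iter=2000)
    ridge.fit(X.values, y)
    w = np.abs(ridge.coef_.ravel()) ** params.gamma
    active = w > 1e-8          # zero ridge coefficient = infinite penalty
    if not active.any():
        return []
    cols = list(X.columns[active])
    Xw = X.values[:, active] * w[active]

    n_folds = int(min(params.n_folds, np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("too few samples in the minority class for cross-validation")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cs = np.logspace(*params.penalty_range, params.n_penalties)

    def l1_fit(Xtr, ytr, c):
        clf = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                 max_iter=500, random_state=seed)
        clf.fit(Xtr, ytr)
        return clf

    import warnings
    from sklearn.metrics import log_loss

    deviance = np.zeros((n_folds, cs.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for f, (tr, te) in enumerate(cv.split(Xw, y)):
            for i, c in enumerate(cs):
                clf = l1_fit(Xw[tr], y[tr], c)
                p = clf.predict_proba(Xw[te])[:, 1]
                deviance[f, i] = 2.0 * log_loss(y[te], p, labels=[0, 1])
        mean_dev = deviance.mean(axis=0)
        se_dev = deviance.std(axis=0, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmin(mean_dev))
        if params.one_se:
            threshold = mean_dev[best] + se_dev[best]
            chosen = int(np.flatnonzero(mean_dev <= threshold)[0])  # strongest penalty
        else:
            chosen = best
        final = l1_fit(Xw, y, cs[chosen])
    coef = final.coef_.ravel()
    return [c for c, b in zip(cols, coef) if abs(b) > 1e-8]


@dataclass
class FittedModel:
    """A fitted low-risk classifier: selected variables, scaling, coefficients."""

    spec: ModelSpec
    variables: list[str]              # final model inputs, in order
    selected: list[str]               # adaptive-LASSO picks (subset of variables)
    standardization: StandardizationParams
    intercept: float
    coefficients: dict[str, float]
    ridge_fallback: bool = False

    def _design(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        need_clin = [v for v in self.variables if v in CLINICAL_VARIABLES]
        if need_clin:
            clin = clinical_matrix(df)
            for v in need_clin:
                cols[v] = clin[v]
        for v in self.variables:
            if v in CLINICAL_VARIABLES:
                continue
            if v not in df.columns:
                raise KeyError(f"missing model variable: {v!r}")
            cols[v] = df[v].astype(float)
        return pd.DataFrame(cols, index=df.index)[self.variables]

    def predict_lesion(self, df: pd.DataFrame) -> np.ndarray:
        """Probability that each lesion (row) is low risk."""
        X, _ = standardize(self._design(df), self.standardization)
        beta = np.array([self.coefficients[v] for v in X.columns])
        eta = self.intercept + X.values @ beta
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_patient(
        self,
        df: pd.DataFrame,
        policy: str = "worst_lesion_truth",
        group_col: str = "patient_id",
        truth_col: str = "true_three_tier",
    ) -> pd.DataFrame:
        """One low-risk probability per patient.

        ``worst_lesion_truth`` evaluates the model on the lesion with
        the highest true three-tier score (the evaluation design used
        when ground-truth labels exist); ``min_prob`` takes the minimum
        predicted low-risk probability over the patient's lesions (a
        deployable pre-biopsy policy).
        """
        if policy == "worst_lesion_truth":
            rows = worst_lesion_rows(df, group_col=group_col, truth_col=truth_col)
            probs = self.predict_lesion(rows)
            return pd.DataFrame({group_col: rows[group_col].values,
                                 "probability": probs, "policy": policy})
        if policy == "min_prob":
            probs = pd.Series(self.predict_lesion(df), index=df.index)
            agg = probs.groupby(df[group_col]).min()
            return pd.DataFrame({group_col: agg.index, "probability": agg.values,
                                 "policy": policy})
        raise ValueError(f"unknown patient policy {policy!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": {**asdict(self.spec)},
            "variables": self.variables,
            "selected": self.selected,
            "standardization": asdict(self.standardization),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "ridge_fallback": self.ridge_fallback,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        payload = json.loads(Path(path).read_text())
        spec_d = payload["spec"]
        sel = spec_d.pop("selection")
        sel["penalty_range"] = tuple(sel["penalty_range"])
        spec = ModelSpec(selection=SelectionParams(**sel), **spec_d)
        return cls(
            spec=spec,
            variables=payload["variables"],
            selected=payload["selected"],
            standardization=StandardizationParams(**payload["standardization"]),
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            ridge_fallback=payload["ridge_fallback"],
        )


def worst_lesion_rows(
    df: pd.DataFrame,
    group_col: str = "patient_id",
    truth_col: str = "true_three_tier",
) -> pd.DataFrame:
    """One row per patient: the lesion with the highest true three-tier score."""
    idx = df.groupby(group_col)[truth_col].idxmax()
    return df.loc[idx.values]


def fit_model(
    spec: ModelSpec,
    df: pd.DataFrame,
    label_col: str = LABEL_COLUMN,
) -> FittedModel:
    """Fit one of the five models on a labeled lesion (or patient) table.

    ``df`` must carry the raw clinical columns (age, psad, dre, pirads)
    for models 1/4/5, the radiomic feature columns the spec's pool
    names, ``HRS6`` for radiomics models, and a boolean/0-1 label
    column (1 = low risk).
    """
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not in dataset")
    y = df[label_col].astype(int).values
    if np.unique(y).size < 2:
        raise ValueError("fit_model requires both classes present")

    blocks = []
    if spec.clinical_variables:
        blocks.append(clinical_matrix(df))
    pool = spec.penalized_pool
    forced = spec.forced_variables
    missing = [c for c in pool + forced if c not in df.columns]
    if missing:
        raise ValueError(f"dataset lacks {len(missing)} pool column(s), "
                         f"e.g. {missing[:5]}")
    if forced:
        blocks.append(df[forced].astype(float))
    if pool:
        blocks.append(df[pool].astype(float))
    X = pd.concat(blocks, axis=1)

    Xs, std_params = standardize(X)

    pool_avail = [c for c in pool if c in Xs.columns]
    if pool_avail:
        selected = adaptive_lasso_select(
            Xs[pool_avail], y, spec.selection, seed=spec.seed)
    else:
        selected = []

    variables = (
        [v for v in spec.clinical_variables if v in Xs.columns]
        + [v for v in forced if v in Xs.columns]
        + selected
    )
    if not variables:
        raise ValueError("no variables available for the final fit")
    Xf = Xs[variables].values

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        final.fit(Xf, y)
    ridge_fallback = False
    if not np.all(np.isfinite(final.coef_)) or np.abs(final.coef_).max() > 30:
        # (quasi-)separation: stabilize with a mild ridge penalty
        logger.warning("model %d: unpenalized fit unstable, refitting with ridge",
                       spec.model_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            final = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000)
            final.fit(Xf, y)
        ridge_fallback = True

    coefs = dict(zip(variables, final.coef_.ravel().tolist()))
    # restrict stored standardization to the final variables
    std = StandardizationParams(
        center={v: std_params.center[v] for v in variables},
        scale={v: std_params.scale[v] for v in variables},
        medians={v: std_params.medians[v] for v in variables},
        dropped=std_params.dropped,
    )
    return FittedModel(
        spec=spec,
        variables=variables,
        selected=selected,
        standardization=std,
        intercept=float(final.intercept_[0]),
        coefficients=coefs,
        ridge_fallback=ridge_fallback,
    )
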