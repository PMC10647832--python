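"""Model performance machinery: ROC/AUC, paired ROC comparison and
bootstrap optimism correction.

* :func:`roc_auc` — AUC as the Mann–Whitney two-sample statistic with
  ties counted 1/2, together with the ROC curve (equal to its
  trapezoidal area).
* :func:`venkatraman_begg_test` — the rank-based permutation test for
  equality of two ROC curves estimated from *paired* data (both markers
  score the same records).  Markers are converted to within-sample
  ranks; the statistic integrates the absolute difference in empirical
  error counts over all rank cut-points; the null is built by randomly
  exchanging the paired ranks per record and re-ranking.
* :func:`optimism_corrected_auc` — Harrell-style internal validation:
  the apparent AUC minus the bootstrap-estimated optimism (mean over
  resamples of AUC(fit on resample, eval on resample) − AUC(same fit,
  eval on original data)).
* :func:`run_experiment` — the full grid: five models × lesion/patient
  level × all/DRE-negative subset × full/intensity-only variant, with
  AUC, optimism-corrected AUC and pairwise comparisons against the
  clinical model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from radiorisk.modeling import (
    FittedModel,
    ModelSpec,
    SelectionParams,
    fit_model,
    standardize,
    worst_lesion_rows,
)

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC of a score for a binary outcome.

    AUC is computed as the normalized Mann–Whitney statistic (ties
    counted 1/2), which equals the trapezoidal area under the empirical
    ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, scores)
    return RocResult(float(auc), fpr, tpr, thr, n_pos, n_neg)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int


def _vb_statistics(ra: np.ndarray, rb: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Venkatraman–Begg statistic for each row of paired rank matrices.

    For a ranked marker, classifying "rank > k" as positive at each
    cut-point k = 1..n-1 yields error count
    e(k) = #{y=1, rank <= k} + #{y=0, rank > k}; the statistic is
    sum_k |e_a(k) - e_b(k)|.  Ties carry mid-ranks: a tied group sits
    entirely on one side of any integer cut-point.
    """
    m, n = ra.shape
    ks = np.arange(1, n, dtype=float)

    def errors(r):
        order = np.argsort(r, axis=1, kind="stable")
        ys = np.broadcast_to(y, (m, n))
        ys_sorted = np.take_along_axis(ys, order, axis=1)
        cumpos = np.concatenate(
            [np.zeros((m, 1)), np.cumsum(ys_sorted, axis=1)], axis=1)
        c = (r[:, :, None] <= ks[None, None, :]).sum(axis=1)  # #{rank <= k}
        pos_le = np.take_along_axis(cumpos, c, axis=1)
        n_neg = n - y.sum()
        return 2 * pos_le - c + n_neg

    return np.abs(errors(ra) - errors(rb)).sum(axis=1)


def venkatraman_begg_test(
    scores_a,
    scores_b,
    labels,
    n_perm: int = 2000,
    seed: int = 0,
) -> ComparisonResult:
    """Permutation test for equality of two paired ROC curves.

    The null distribution exchanges the two markers' ranks within each
    record with probability 1/2 and re-ranks; the p-value is
    ``(1 + #{perm >= observed}) / (n_perm + 1)``.  The statistic is
    invariant to strictly monotone transforms of either score.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError(
            f"length mismatch: scores_a {a.shape}, scores_b {b.shape}, labels {y.shape}")
    if y.min() == y.max():
        raise ValueError("venkatraman_begg_test requires both classes present")

    ra = rankdata(a)
    rb = rankdata(b)
    observed = float(_vb_statistics(ra[None, :], rb[None, :], y)[0])

    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm, a.size)) < 0.5
    pa = np.where(swap, rb, ra)
    pb = np.where(swap, ra, rb)
    pa = rankdata(pa, axis=1)
    pb = rankdata(pb, axis=1)
    perm_stats = _vb_statistics(pa, pb, y)
    p = (1.0 + np.sum(perm_stats >= observed - 1e-9)) / (n_perm + 1.0)
    return ComparisonResult(observed, float(p), n_perm, seed)


@dataclass
class OptimismResult:
    apparent_auc: float
    optimism: float
    corrected_auc: float
    n_boot: int
    n_redrawn: int
    seed: int


def optimism_corrected_auc(
    df: pd.DataFrame,
    model_builder,
    n_boot: int = 1000,
    seed: int = 0,
    label_col: str = "low_risk",
) -> OptimismResult:
    """Bootstrap optimism-corrected AUC (Harrell internal validation).

    ``model_builder(train_df)`` must return a callable mapping a
    DataFrame to scores, deterministically given its input.  Resamples
    containing a single outcome class are redrawn (counted and logged).
    """
    y = df[label_col].astype(int).values
    rng = np.random.default_rng(seed)
    score_full = model_builder(df)
    apparent = roc_auc(score_full(df), y).auc

    optimisms = []
    n_redrawn = 0
    n = len(df)
    while len(optimisms) < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            n_redrawn += 1
            continue
        boot = df.iloc[idx]
        score_b = model_builder(boot)
        auc_boot = roc_auc(score_b(boot), yb).auc
        auc_orig = roc_auc(score_b(df), y).auc
        optimisms.append(auc_boot - auc_orig)
    if n_redrawn:
        logger.info("optimism bootstrap: redrew %d single-class resamples", n_redrawn)
    optimism = float(np.mean(optimisms))
    return OptimismResult(float(apparent), optimism, float(apparent - optimism),
                          n_boot, n_redrawn, seed)


# ---------------------------------------------------------------------------
# experiment grid


@dataclass
class ExperimentConfig:
    """Settings of the model-comparison grid."""

    model_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    variants: tuple[str, ...] = ("full",)          # and/or "intensity_only"
    subsets: tuple[str, ...] = ("all", "dre0")
    levels: tuple[str, ...] = ("lesion", "patient")
    selection: SelectionParams = field(default_factory=SelectionParams)
    patient_refit: bool = True     # refit on worst-lesion rows for patient level
    n_boot: int = 200              # optimism bootstrap replicates (0 disables)
    n_perm: int = 500              # Venkatraman-Begg permutations (0 disables)
    seed: int = 0


def _refit_builder(model: FittedModel, label_col: str):
    """Optimism model-builder: logistic refit on the already-selected variables.

    Variable selection is performed once on the full data (matching a
    single reported variable list); the bootstrap re-estimates only the
    logistic coefficients on the fixed selected set.
    """
    from sklearn.linear_model import LogisticRegression

    def build(train: pd.DataFrame):
        X, _ = standardize(model._design(train), model.standardization)
        yb = train[label_col].astype(int).values
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        lr.fit(X.values, yb)

        def score(eval_df: pd.DataFrame) -> np.ndarray:
            Xe, _ = standardize(model._design(eval_df), model.standardization)
            return lr.predict_proba(Xe.values)[:, 1]
        return score
    return build


def run_experiment(
    lesion_df: pd.DataFrame,
    config: ExperimentConfig | None = None,
    label_col: str = "low_risk",
) -> pd.DataFrame:
    """Fit and evaluate the model grid on a labeled lesion table.

    ``lesion_df`` needs the clinical columns, the radiomic features,
    ``HRS6``, ``patient_id``, ``dre``, ``true_three_tier`` (for the
    worst-lesion patient policy) and the label column.  Returns one row
    per grid cell with AUC, optimism-corrected AUC and the
    Venkatraman–Begg p-value against the clinical model (model 1).
    Cells whose evaluation subset has a single class are marked
    undefined (NaN) and logged.
    """
    config = config or ExperimentConfig()
    results = []
    for variant in config.variants:
        intensity_only = variant == "intensity_only"
        fitted: dict[tuple[int, str], FittedModel] = {}
        scores: dict[tuple[int, str], pd.Series] = {}
        frames: dict[str, pd.DataFrame] = {"lesion": lesion_df}
        if "patient" in config.levels:
            frames["patient"] = worst_lesion_rows(lesion_df)

        for level in config.levels:
            frame = frames[level]
            train = frame if (level == "lesion" or config.patient_refit) else lesion_df
            for mid in config.model_ids:
                spec = ModelSpec(mid, intensity_only=intensity_only,
                                 selection=config.selection, seed=config.seed)
                model = fit_model(spec, train, label_col=label_col)
                fitted[(mid, level)] = model
                scores[(mid, level)] = pd.Series(
                    model.predict_lesion(frame), index=frame.index)

        for level in config.levels:
            frame = frames[level]
            for subset in config.subsets:
                sel = frame.index if subset == "all" else frame.index[frame["dre"] == 0]
                sub = frame.loc[sel]
                y = sub[label_col].astype(int).values
                for mid in config.model_ids:
                    model = fitted[(mid, level)]
                    row = {
                        "model": mid, "level": level, "subset": subset,
                        "variant": variant, "n": len(sub),
                        "n_pos": int(y.sum()), "n_neg": int(len(y) - y.sum()),
                        "n_selected": len(model.selected),
                        "auc": np.nan, "oc_auc": np.nan, "p_vs_model1": np.nan,
                    }
                    if len(np.unique(y)) < 2:
                        logger.warning("grid cell %s undefined: single class", row)
                        results.append(row)
                        continue
                    s = scores[(mid, level)].loc[sel].values
                    row["auc"] = roc_auc(s, y).auc
                    if config.n_boot > 0:
                        row["oc_auc"] = optimism_corrected_auc(
                            sub, _refit_builder(model, label_col),
                            n_boot=config.n_boot, seed=config.seed,
                            label_col=label_col,
                        ).corrected_auc
                    if config.n_perm > 0 and mid != 1 and 1 in config.model_ids:
                        s1 = scores[(1, level)].loc[sel].values
                        row["p_vs_model1"] = venkatraman_begg_test(
                            s, s1, y, n_perm=config.n_perm, seed=config.seed,
                        ).p_value
                    results.append(row)
    return pd.DataFrame(results)
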