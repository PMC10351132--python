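"""Cox risk-model construction and evaluation.

Univariate Cox screen, 1:1 cohort split, L1-penalized Cox path with
cross-validated lambda, bidirectional stepwise-AIC refinement, linear risk
score with median stratification, a from-scratch log-rank test,
IPCW time-dependent AUC, and a multivariate Cox fit with a binned
calibration table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .io_core import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (365, 1095, 1825)


@dataclass
class RiskModel:
    """Ordered (lncRNA, coefficient) terms plus the training-median cutoff."""

    terms: list[tuple[str, float]]
    training_median: float = 0.0

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("risk model must have at least one term")
        if not all(np.isfinite(c) for _, c in self.terms):
            raise ValueError("coefficients must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.terms]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.terms], dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {"terms": [[g, c] for g, c in self.terms], "training_median": self.training_median},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        obj = json.loads(text)
        return cls(
            terms=[(str(g), float(c)) for g, c in obj["terms"]],
            training_median=float(obj.get("training_median", 0.0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


@dataclass
class SurvivalFit:
    """Flattened Cox fit: one row per covariate plus fit-level stats."""

    table: pd.DataFrame  # index covariate; coef, hazard_ratio, ci_low, ci_high, pvalue
    log_likelihood: float
    aic: float


def _fit_to_survivalfit(cph: CoxPHFitter) -> SurvivalFit:
    s = cph.summary
    table = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "pvalue": s["p"],
        }
    )
    return SurvivalFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        aic=float(cph.AIC_partial_),
    )


def _cox_frame(expr: ExpressionMatrix, clin: ClinicalTable, genes: list[str]) -> pd.DataFrame:
    samples = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    df = expr.values.loc[genes, samples].T.copy()
    df["os_time"] = clin.data.loc[samples, "os_time"]
    df["os_status"] = clin.data.loc[samples, "os_status"]
    return df


def _fit_cox(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="os_time", event_col="os_status")
    return cph


def univariate_screen(
    expr_lnc: ExpressionMatrix,
    clin: ClinicalTable,
    p_cut: float = 0.05,
) -> tuple[list[str], dict[str, SurvivalFit]]:
    """One single-covariate Cox fit per lncRNA; keep Wald p < p_cut."""
    if clin.n_events < 10:
        raise ValueError(f"need >= 10 events, have {clin.n_events}")
    fits: dict[str, SurvivalFit] = {}
    passing: list[str] = []
    for gene in expr_lnc.gene_ids:
        df = _cox_frame(expr_lnc, clin, [gene])
        try:
            cph = _fit_cox(df)
        except Exception as exc:  # non-convergence
            logger.warning("univariate Cox failed for %s: %s", gene, exc)
            continue
        fit = _fit_to_survivalfit(cph)
        fits[gene] = fit
        if float(fit.table.loc[gene, "pvalue"]) < p_cut:
            passing.append(gene)
    return passing, fits


def split_cohort(clin: ClinicalTable, ratio: float = 0.5, seed: int = 0) -> tuple[list[str], list[str]]:
    """Random train/test partition with sizes differing by at most one."""
    samples = clin.sample_ids
    if len(samples) < 20:
        raise ValueError("need at least 20 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    n_train = int(round(ratio * len(samples)))
    train = sorted(samples[i] for i in perm[:n_train])
    test = sorted(samples[i] for i in perm[n_train:])
    return train, test


def _breslow_loglik(time: np.ndarray, status: np.ndarray, eta: np.ndarray) -> float:
    """Breslow log partial likelihood of risk scores ``eta``."""
    order = np.argsort(-time, kind="stable")
    time, status, eta = time[order], status[order], eta[order]
    log_cum = np.logaddexp.accumulate(eta)
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        at_risk = log_cum[j - 1]
        for k in range(i, j):
            if status[k]:
                ll += eta[k] - at_risk
        i = j
    return float(ll)


def lasso_cox_select(
    expr_lnc_train: ExpressionMatrix,
    clin_train: ClinicalTable,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """L1-penalized Cox over a log-spaced lambda path.

    Lambda is chosen by k-fold cross-validated held-out partial likelihood
    (the lambda.min analogue); returns the nonzero coefficients at that
    lambda.  An all-zero solution returns an empty dict with a warning.
    """
    genes = expr_lnc_train.gene_ids
    if len(genes) < 2:
        raise ValueError("need at least 2 candidate lncRNAs")
    df = _cox_frame(expr_lnc_train, clin_train, genes)
    X = df[genes].to_numpy()
    y = Surv.from_arrays(df["os_status"].astype(bool), df["os_time"])
    time = df["os_time"].to_numpy(dtype=float)
    status = df["os_status"].to_numpy(dtype=int)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50)
    path.fit(X, y)
    alphas = path.alphas_

    n_folds = min(n_folds, max(2, int(status.sum() // 2)))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_ll = np.zeros(len(alphas))
    for train_idx, test_idx in kf.split(X):
        if status[train_idx].sum() == 0 or status[test_idx].sum() == 0:
            continue
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold.fit(X[train_idx], y[train_idx])
        except Exception as exc:
            logger.warning("coxnet CV fold failed: %s", exc)
            continue
        for ai, alpha in enumerate(alphas):
            eta = fold.predict(X[test_idx], alpha=alpha)
            cv_ll[ai] += _breslow_loglik(time[test_idx], status[test_idx], np.asarray(eta))
    best = int(np.argmax(cv_ll))
    coefs = path.coef_[:, best] if path.coef_.ndim == 2 else path.coef_
    selected = {g: float(c) for g, c in zip(genes, coefs) if c != 0.0}
    if not selected:
        logger.warning("lasso path fully shrunk: no features retained at lambda.min")
    return selected


def stepwise_aic(
    expr_lnc_train: ExpressionMatrix,
    clin_train: ClinicalTable,
    candidates: list[str] | None = None,
) -> RiskModel:
    """Bidirectional stepwise search minimizing AIC over unpenalized Cox fits.

    Starts from the full candidate model; at each step evaluates all
    single-term removals and additions and takes the move with the largest
    AIC decrease, stopping when none improves.  Coefficients of the final
    fit become the model terms; the cutoff is the training-median score.
    """
    candidates = candidates if candidates is not None else expr_lnc_train.gene_ids
    if not candidates:
        raise ValueError("need at least one candidate")
    cache: dict[frozenset, float | None] = {}

    def aic_of(current: frozenset) -> float | None:
        if current in cache:
            return cache[current]
        if not current:
            cache[current] = None
            return None
        df = _cox_frame(expr_lnc_train, clin_train, sorted(current))
        try:
            cph = _fit_cox(df)
            cache[current] = float(cph.AIC_partial_)
        except Exception as exc:
            logger.warning("stepwise fit failed for %s: %s", sorted(current), exc)
            cache[current] = None
        return cache[current]

    current = frozenset(candidates)
    current_aic = aic_of(current)
    if current_aic is None:
        raise RuntimeError("full model did not converge")
    while True:
        moves: list[tuple[float, frozenset]] = []
        for g in sorted(current):
            sub = current - {g}
            a = aic_of(sub)
            if a is not None:
                moves.append((a, sub))
        for g in sorted(set(candidates) - current):
            sup = current | {g}
            a = aic_of(sup)
            if a is not None:
                moves.append((a, sup))
        if not moves:
            break
        best_aic, best_set = min(moves, key=lambda t: (t[0], tuple(sorted(t[1]))))
        if best_aic >= current_aic - 1e-10:
            break
        current, current_aic = best_set, best_aic

    final_genes = sorted(current)
    df = _cox_frame(expr_lnc_train, clin_train, final_genes)
    cph = _fit_cox(df)
    terms = [(g, float(cph.params_[g])) for g in final_genes]
    model = RiskModel(terms=terms)
    scores = risk_score(model, expr_lnc_train)
    model.training_median = float(np.median(scores.to_numpy()))
    return model


def risk_score(model: RiskModel, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample inner product of model coefficients with expression."""
    missing = [g for g in model.gene_ids if g not in expr.values.index]
    if missing:
        raise KeyError(f"model genes missing from matrix: {missing}")
    X = expr.values.loc[model.gene_ids].to_numpy()
    return pd.Series(model.coefficients @ X, index=expr.sample_ids, name="risk_score")


def logrank_test(
    time: np.ndarray, status: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test from the observed-minus-expected form.

    Returns the 1-df chi-square statistic and its upper-tail p-value.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    event_times = np.unique(time[status == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_t = int(at_risk.sum())
        n1_t = int((at_risk & group).sum())
        d_t = int(((time == t) & (status == 1)).sum())
        d1_t = int(((time == t) & (status == 1) & group).sum())
        o_minus_e += d1_t - d_t * n1_t / n_t
        if n_t > 1:
            var += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def stratify_and_test(
    scores: pd.Series, clin: ClinicalTable, cutoff: float
) -> tuple[pd.Series, float, float]:
    """Split at ``score > cutoff`` into high/low and log-rank test the strata."""
    common = [s for s in scores.index if s in set(clin.sample_ids)]
    scores = scores.loc[common]
    high = scores > cutoff
    if high.all() or not high.any():
        raise ValueError("cutoff produces an empty stratum")
    labels = pd.Series(np.where(high, "high", "low"), index=scores.index, name="risk_group")
    chi2, p = logrank_test(
        clin.data.loc[common, "os_time"].to_numpy(),
        clin.data.loc[common, "os_status"].to_numpy(),
        high.to_numpy(),
    )
    return labels, chi2, p


def time_dependent_auc(
    scores: pd.Series,
    clin: ClinicalTable,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    min_events: int = 5,
) -> dict[float, float]:
    """Cumulative/dynamic AUC with KM inverse-censoring weights per horizon.

    Horizons with fewer than ``min_events`` prior events or beyond the last
    observed time are skipped with a warning.
    """
    common = [s for s in scores.index if s in set(clin.sample_ids)]
    time = clin.data.loc[common, "os_time"].to_numpy(dtype=float)
    status = clin.data.loc[common, "os_status"].to_numpy(dtype=int)
    est = scores.loc[common].to_numpy(dtype=float)
    y = Surv.from_arrays(status.astype(bool), time)
    out: dict[float, float] = {}
    for h in horizons:
        n_events = int(((time <= h) & (status == 1)).sum())
        if h >= time.max() or n_events < min_events:
            logger.warning("horizon %s skipped (%d prior events, max time %.1f)", h, n_events, time.max())
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc, _ = cumulative_dynamic_auc(y, y, est, [h])
        out[float(h)] = float(auc[0])
    return out


def _encode_covariates(features: pd.DataFrame) -> pd.DataFrame:
    """Categorical columns to indicator contrasts; reference = first level
    alphabetically.  Collinear columns are dropped with a warning."""
    encoded = []
    for col in features.columns:
        ser = features[col]
        if ser.dtype.kind in "OUSb" or isinstance(ser.dtype, pd.CategoricalDtype):
            levels = sorted(ser.astype(str).unique())
            for lev in levels[1:]:
                encoded.append(pd.Series((ser.astype(str) == lev).astype(float), name=f"{col}_{lev}"))
        else:
            encoded.append(ser.astype(float))
    X = pd.concat(encoded, axis=1)
    # drop exactly collinear columns by greedy rank check
    keep: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy()
        centered = trial - trial.mean(axis=0)
        if np.linalg.matrix_rank(centered) == len(keep) + 1:
            keep.append(col)
        else:
            logger.warning("dropping collinear covariate %r", col)
    return X[keep]


def multivariate_cox(
    features: pd.DataFrame,
    clin: ClinicalTable,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
    n_bins: int = 10,
) -> tuple[SurvivalFit, pd.Series, pd.DataFrame]:
    """Single Cox fit of the risk score plus clinical covariates.

    Returns the fit, the per-sample linear predictor (the nomogram score) and
    a binned calibration table (predicted vs Kaplan-Meier observed survival
    per predicted-survival bin at each horizon).
    """
    common = [s for s in features.index if s in set(clin.sample_ids)]
    X = _encode_covariates(features.loc[common])
    df = X.copy()
    df["os_time"] = clin.data.loc[common, "os_time"]
    df["os_status"] = clin.data.loc[common, "os_status"]
    cph = _fit_cox(df)
    fit = _fit_to_survivalfit(cph)
    lin_pred = pd.Series(
        cph.predict_log_partial_hazard(df).to_numpy(), index=df.index, name="linear_predictor"
    )

    rows = []
    for h in horizons:
        if h >= df["os_time"].max():
            logger.warning("calibration horizon %s beyond last observed time; skipped", h)
            continue
        pred_surv = cph.predict_survival_function(df, times=[h]).iloc[0]
        try:
            bins = pd.qcut(pred_surv, q=n_bins, labels=False, duplicates="drop")
        except ValueError:
            continue
        for b in sorted(pd.unique(bins)):
            members = pred_surv.index[bins == b]
            km = KaplanMeierFitter()
            km.fit(df.loc[members, "os_time"], df.loc[members, "os_status"])
            rows.append(
                {
                    "horizon": h,
                    "bin": int(b),
                    "n": len(members),
                    "predicted": float(pred_surv.loc[members].mean()),
                    "observed": float(km.predict(h)),
                }
            )
    calibration = pd.DataFrame(rows)
    return fit, lin_pred, calibration
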