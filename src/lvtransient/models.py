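"""Prognostic evaluation: endpoint adjudication, univariate summaries,
backward stepwise LDA/Cox selection, and repeated cross-validated
AUC / C-index performance.

The composite clinical endpoint (MACE: all-cause death, reinfarction,
new congestive heart failure within 12 months) is adjudicated with one
contribution per patient, chosen by priority death > reinfarction >
heart failure. Variable selection is backward stepwise: all candidates
enter, the least significant is removed until every retained variable
meets p < 0.05 — with LDA significance approximated by Wald p-values of
a binomial (logistic) GLM refit, and Cox significance by
partial-likelihood Wald tests. Model performance is reported as
resubstitution plus repeated stratified 10-fold cross-validation (one
pooled out-of-fold AUC or C-index per random split, 100 splits by
default); per-split distributions are compared with the Wilcoxon
rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
K_FOLDS_DEFAULT = 10
N_SPLITS_DEFAULT = 100
HORIZON_MONTHS_DEFAULT = 12.0

OUTCOME_COL = "mace"
TIME_COL = "time_months"
CENSOR_COL = "censored"


class ModelInputError(ValueError):
    """Raised on malformed model inputs."""


# ------------------------------------------------------ endpoint adjudication

@dataclass
class EventRecord:
    """Component events for one patient; times in months since baseline."""

    patient_id: str
    death_month: float | None = None
    reinfarction_month: float | None = None
    chf_month: float | None = None


_PRIORITY = ("death", "reinfarction", "chf")


def adjudicate_endpoint(records: list[EventRecord],
                        horizon: float = HORIZON_MONTHS_DEFAULT) -> pd.DataFrame:
    """Composite-endpoint labels with one contribution per patient.

    MACE = 1 iff any component event occurs within the horizon; the
    contributing component is chosen by priority death > reinfarction >
    congestive heart failure, and the event time is that component's
    time. Event-free patients are censored at the horizon.
    """
    rows = []
    for rec in records:
        times = {
            "death": rec.death_month,
            "reinfarction": rec.reinfarction_month,
            "chf": rec.chf_month,
        }
        component, when = None, None
        for name in _PRIORITY:
            tt = times[name]
            if tt is not None and 0 < tt <= horizon:
                component, when = name, float(tt)
                break
        if component is None:
            rows.append({"patient_id": rec.patient_id, OUTCOME_COL: 0,
                         TIME_COL: horizon, CENSOR_COL: True,
                         "component": None})
        else:
            rows.append({"patient_id": rec.patient_id, OUTCOME_COL: 1,
                         TIME_COL: when, CENSOR_COL: False,
                         "component": component})
    return pd.DataFrame(rows)


def cohort_accounting(total_considered: int, exclusions: dict[str, int]) -> dict:
    """Patient-flow arithmetic: considered minus exclusion categories."""
    excluded = int(sum(exclusions.values()))
    included = int(total_considered) - excluded
    if included < 0:
        raise ModelInputError("exclusions exceed the considered cohort")
    return {"considered": int(total_considered), "excluded": excluded,
            "included": included, **exclusions}


# ------------------------------------------------------------ rank metrics

def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ModelInputError("AUC needs both classes present")
    ranks = rankdata(scores)
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u1 / (n1 * n0))


def c_index(risk, time, event_flag) -> float:
    """Harrell's concordance of a risk score against event times.

    Higher risk should mean earlier events; ties in risk count 1/2.
    Comparable pairs follow the usual rule (earlier member must be an
    observed event).
    """
    from lifelines.utils import concordance_index

    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event_flag).astype(bool)
    if not event.any():
        raise ModelInputError("C-index needs at least one observed event")
    # lifelines scores "higher predicted value = longer survival"
    return float(concordance_index(time, -risk, event))


# ------------------------------------------------------ univariate summary

def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    return (float(np.median(x)), float(np.percentile(x, 25)),
            float(np.percentile(x, 75)))


def univariate_summary(table: pd.DataFrame, feature: str,
                       k: int = K_FOLDS_DEFAULT,
                       n_splits: int = N_SPLITS_DEFAULT,
                       seed: int = 0) -> dict:
    """Per-feature row: median (IQR) overall and per class, Wilcoxon
    rank-sum p, univariate repeated-CV LDA AUC, and a per-SD Cox hazard
    ratio with 95% CI.

    Mirrors the summary-table layout median (IQR) | AUC_k | Pval | HR |
    HR Pval. Constant features get p = 1, AUC = 0.5 and an
    undefined-flagged HR.
    """
    sub = table[[feature, OUTCOME_COL, TIME_COL, CENSOR_COL]].dropna(
        subset=[feature])
    x = sub[feature].to_numpy(dtype=float)
    y = sub[OUTCOME_COL].to_numpy(dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ModelInputError("need >= 2 non-missing values per class")

    row: dict = {"feature": feature, "n": int(len(sub))}
    for name, mask in (("all", np.ones_like(y, bool)),
                       ("mace", y == 1), ("no_mace", y == 0)):
        med, q25, q75 = _median_iqr(x[mask])
        row[f"median_{name}"] = med
        row[f"iqr_{name}"] = (q25, q75)

    if np.ptp(x) == 0:
        row.update({"wilcoxon_p": 1.0, "auc_k": 0.5, "hr": None,
                    "hr_ci": None, "hr_p": None, "hr_undefined": True})
        return row

    row["wilcoxon_p"] = float(
        mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided").pvalue)

    perf = evaluate_cv(sub, [feature], family="lda", k=k,
                       n_splits=n_splits, seed=seed)
    row["auc_k"] = perf.median

    from lifelines import CoxPHFitter

    df = sub.copy()
    df["_z"] = (x - x.mean()) / x.std(ddof=0)
    df["_event"] = (~df[CENSOR_COL].astype(bool)).astype(int)
    cph = CoxPHFitter()
    cph.fit(df[["_z", TIME_COL, "_event"]], duration_col=TIME_COL,
            event_col="_event")
    s = cph.summary.loc["_z"]
    row.update({
        "hr": float(s["exp(coef)"]),
        "hr_ci": (float(s["exp(coef) lower 95%"]),
                  float(s["exp(coef) upper 95%"])),
        "hr_p": float(s["p"]),
        "hr_undefined": False,
    })
    return row


# -------------------------------------------------------- stepwise selection

@dataclass
class StepwiseModel:
    family: str
    selected_variables: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n_used: int
    elimination_trace: list[dict] = field(default_factory=list)
    lda_coefficients: dict[str, float] | None = None


def _glm_pvalues(df: pd.DataFrame, variables: list[str]):
    """Wald p-values from a binomial GLM (logistic) fit."""
    import statsmodels.api as sm

    X = sm.add_constant(df[variables].to_numpy(dtype=float))
    y = df[OUTCOME_COL].to_numpy(dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse[1:] > 1e3):
        raise np.linalg.LinAlgError("unstable logistic fit")
    p = dict(zip(variables, res.pvalues[1:]))
    coef = dict(zip(variables, res.params[1:]))
    return p, coef


def _cox_pvalues(df: pd.DataFrame, variables: list[str], standardize: bool):
    from lifelines import CoxPHFitter

    d = df[variables + [TIME_COL]].copy()
    d["_event"] = (~df[CENSOR_COL].astype(bool)).astype(int)
    if standardize:
        for v in variables:
            sd = d[v].std(ddof=0)
            if sd == 0:
                raise np.linalg.LinAlgError(f"constant predictor {v}")
            d[v] = (d[v] - d[v].mean()) / sd
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(d, duration_col=TIME_COL, event_col="_event")
    p = {v: float(cph.summary.loc[v, "p"]) for v in variables}
    coef = {v: float(cph.summary.loc[v, "coef"]) for v in variables}
    return p, coef


def _drop_collinear(df: pd.DataFrame, variables: list[str]) -> list[str]:
    """Later-listed variables that break full column rank."""
    dropped = []
    X = df[variables].to_numpy(dtype=float)
    keep = list(range(len(variables)))
    while keep:
        sub = X[:, keep]
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(sub)), sub]))
        if rank == len(keep) + 1:
            break
        dropped.append(variables[keep[-1]])
        keep = keep[:-1]
    return dropped


def backward_stepwise(table: pd.DataFrame, candidates: list[str],
                      family: str = "lda", alpha: float = ALPHA_DEFAULT,
                      standardize_cox: bool = True) -> StepwiseModel:
    """Backward elimination until all retained variables meet p < alpha.

    All candidates enter; at each step the variable with the largest
    p-value is removed (ties resolved towards the later-listed one).
    Patients with missing data in any candidate are excluded up front.
    Collinear or separation-breaking variables are dropped with a logged
    reason. An empty selection is a valid result.
    """
    if family not in ("lda", "cox"):
        raise ModelInputError("family must be 'lda' or 'cox'")
    if not candidates:
        raise ModelInputError("need at least one candidate")
    needed = candidates + [OUTCOME_COL, TIME_COL, CENSOR_COL]
    df = table.dropna(subset=[c for c in needed if c in table.columns])
    n_used = len(df)
    if n_used < 10 * max(1, len(candidates)) and n_used < len(table):
        logger.warning("only %d complete cases for %d candidates",
                       n_used, len(candidates))

    variables = list(candidates)
    trace: list[dict] = []
    for v in _drop_collinear(df, variables):
        variables.remove(v)
        trace.append({"removed": v, "p": None, "reason": "collinear"})
        logger.info("dropped collinear variable %s", v)

    coefs: dict[str, float] = {}
    pvals: dict[str, float] = {}
    while variables:
        try:
            if family == "lda":
                pvals, coefs = _glm_pvalues(df, variables)
            else:
                pvals, coefs = _cox_pvalues(df, variables, standardize_cox)
        except Exception as err:  # separation / non-convergence
            victim = variables[-1]
            variables = variables[:-1]
            trace.append({"removed": victim, "p": None,
                          "reason": f"fit failure: {type(err).__name__}"})
            logger.info("dropped %s after fit failure (%s)", victim, err)
            continue
        worst = max(variables,
                    key=lambda v: (pvals[v], variables.index(v)))
        if pvals[worst] < alpha:
            break
        variables = [v for v in variables if v != worst]
        trace.append({"removed": worst, "p": float(pvals[worst]),
                      "reason": "p >= alpha"})
    if not variables:
        coefs, pvals = {}, {}

    lda_coefs = None
    if family == "lda" and variables:
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis().fit(
            df[variables].to_numpy(dtype=float),
            df[OUTCOME_COL].to_numpy(dtype=int))
        lda_coefs = dict(zip(variables, lda.coef_[0].astype(float)))

    return StepwiseModel(
        family=family, selected_variables=variables,
        coefficients={v: float(coefs[v]) for v in variables},
        p_values={v: float(pvals[v]) for v in variables},
        n_used=n_used, elimination_trace=trace,
        lda_coefficients=lda_coefs,
    )


# ------------------------------------------------------------ CV evaluation

@dataclass
class CVPerformance:
    metric: str                 # "auc" or "c_index"
    resubstitution: float
    values: np.ndarray          # one value per random split
    median: float
    iqr: tuple[float, float]
    k: int
    n_splits: int
    seed: int

    @classmethod
    def from_values(cls, metric, resub, values, k, n_splits, seed):
        values = np.asarray(values, dtype=float)
        return cls(metric=metric, resubstitution=float(resub), values=values,
                   median=float(np.median(values)),
                   iqr=(float(np.percentile(values, 25)),
                        float(np.percentile(values, 75))),
                   k=k, n_splits=n_splits, seed=seed)


def _fit_score(train: pd.DataFrame, test: pd.DataFrame,
               variables: list[str], family: str,
               standardize_cox: bool) -> np.ndarray:
    if family == "lda":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis().fit(
            train[variables].to_numpy(dtype=float),
            train[OUTCOME_COL].to_numpy(dtype=int))
        return lda.decision_function(test[variables].to_numpy(dtype=float))
    from lifelines import CoxPHFitter

    d = train[variables + [TIME_COL]].copy()
    d["_event"] = (~train[CENSOR_COL].astype(bool)).astype(int)
    mu = d[variables].mean()
    sd = d[variables].std(ddof=0).replace(0.0, 1.0)
    if standardize_cox:
        d[variables] = (d[variables] - mu) / sd
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(d, duration_col=TIME_COL, event_col="_event")
    te = test[variables].copy()
    if standardize_cox:
        te = (te - mu) / sd
    return np.log(cph.predict_partial_hazard(te).to_numpy(dtype=float))


def evaluate_cv(table: pd.DataFrame, variables: list[str],
                family: str = "lda", k: int = K_FOLDS_DEFAULT,
                n_splits: int = N_SPLITS_DEFAULT, seed: int = 0,
                standardize_cox: bool = True) -> CVPerformance:
    """Resubstitution + repeated stratified k-fold performance.

    The variable list stays fixed (no per-fold reselection); per random
    split, out-of-fold scores are pooled into one AUC (LDA) or C-index
    (Cox). Split s uses fold seed = seed + s. A split whose folds
    cannot be fit (e.g. an event-free training fold) is re-drawn with an
    offset seed and logged.
    """
    from sklearn.model_selection import StratifiedKFold

    if family not in ("lda", "cox"):
        raise ModelInputError("family must be 'lda' or 'cox'")
    if not variables:
        raise ModelInputError("need at least one variable")
    needed = variables + [OUTCOME_COL, TIME_COL, CENSOR_COL]
    df = table.dropna(subset=[c for c in needed if c in table.columns])
    df = df.reset_index(drop=True)
    y = df[OUTCOME_COL].to_numpy(dtype=int)

    def _metric(scores) -> float:
        if family == "lda":
            return auc(scores, y)
        return c_index(scores, df[TIME_COL].to_numpy(),
                       ~df[CENSOR_COL].to_numpy(dtype=bool))

    resub = _metric(_fit_score(df, df, variables, family, standardize_cox))

    values = np.empty(n_splits)
    for s in range(n_splits):
        attempt, done = 0, False
        while not done:
            fold_seed = seed + s + attempt * 10_000
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=fold_seed % (2 ** 31))
            scores = np.empty(len(df))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    for tr, te in skf.split(np.zeros(len(df)), y):
                        scores[te] = _fit_score(df.iloc[tr], df.iloc[te],
                                                variables, family,
                                                standardize_cox)
                done = True
            except Exception as err:
                attempt += 1
                logger.info("re-drawing split %d after %s", s, err)
                if attempt > 5:
                    raise
        values[s] = _metric(scores)
    metric_name = "auc" if family == "lda" else "c_index"
    return CVPerformance.from_values(metric_name, resub, values, k,
                                     n_splits, seed)


def compare_performance(a: CVPerformance, b: CVPerformance) -> float:
    """Two-sided Wilcoxon rank-sum p-value on per-split distributions."""
    if a.metric != b.metric:
        raise ModelInputError("performances measure different metrics")
    if a.n_splits != b.n_splits:
        raise ModelInputError("mismatched numbers of splits")
    pooled = np.concatenate([a.values, b.values])
    if np.ptp(pooled) == 0:
        return 1.0
    return float(mannwhitneyu(a.values, b.values,
                              alternative="two-sided").pvalue)
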