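"""Exhaustive search for prognostic gene-expression signatures.

Patient cohorts (log-scaled expression, recurrence status, follow-up) are
first dichotomized into an event class (recurrence within a horizon) and a
control class (recurrence-free with sufficiently long follow-up); patients
between the two rules form a "grey zone" and are excluded, as are patients
with unknown status or implausibly early events.

For every candidate gene subset a linear classifier

    R(e_1, …, e_d) = w_1 e_1 + … + w_d e_d − ρ

is fitted with a linear-kernel SVM using class weights inversely
proportional to class sizes.  Expressions are (0, 1)-scaled with means and
standard deviations estimated on the *training* cohort only; the same
scaler is applied to filtration and validation cohorts, so no information
leaks out of training.  A patient is assigned to the high-risk group when
R >= 0.

Candidates failing sensitivity/specificity thresholds on the training
cohort (default 60%) or on any filtration cohort (default 50%) are
discarded; survivors are ranked by the mean AUC over the training and
filtration cohorts.  Validation metrics and Kaplan–Meier / log-rank
survival comparisons are computed on the held-out validation cohort only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "CohortDataset",
    "LabeledCohort",
    "DichotomizationScheme",
    "COLORECTAL_SCHEME",
    "BREAST_SCHEME",
    "LinearSignature",
    "SignatureEvaluation",
    "SearchEntry",
    "read_cohort",
    "dichotomize",
    "fit_signature",
    "risk_scores",
    "evaluate",
    "exhaustive_search",
    "km_logrank",
    "cross_validate",
]

RECURRED = "recurred"
RECURRENCE_FREE = "recurrence_free"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class CohortDataset:
    """One patient cohort: expression plus recurrence follow-up.

    ``expression`` is patients × genes (log-scaled values); ``status`` holds
    ``recurred`` / ``recurrence_free`` / ``unknown`` per patient and
    ``time_months`` the recurrence time (events) or last follow-up
    (controls).  ``role`` is training / filtration / validation.
    """

    expression: pd.DataFrame
    status: pd.Series
    time_months: pd.Series
    role: str = "training"

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.status.index) or not self.expression.index.equals(
            self.time_months.index
        ):
            raise ValueError("expression, status and time must share the same patient index")
        bad = set(self.status.unique()) - {RECURRED, RECURRENCE_FREE, UNKNOWN}
        if bad:
            raise ValueError(f"unknown recurrence status values {sorted(bad)}")
        if (self.time_months < 0).any():
            raise ValueError("follow-up/event times must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)


@dataclass(frozen=True)
class LabeledCohort:
    """A dichotomized cohort: expression plus binary event labels."""

    expression: pd.DataFrame
    event: pd.Series  # True = event class (recurrence), False = control
    role: str = "training"
    exclusions: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.event).sum())


@dataclass(frozen=True)
class DichotomizationScheme:
    """Event/control windows, in months.

    Event: recurrence in (``min_event_months``, ``event_horizon_months``].
    Control: recurrence-free with follow-up >= ``control_min_followup_months``.
    """

    event_horizon_months: float
    control_min_followup_months: float
    min_event_months: float = 0.0

    def __post_init__(self) -> None:
        if self.control_min_followup_months < self.event_horizon_months:
            raise ValueError("control minimum follow-up must be >= the event horizon")
        if self.min_event_months < 0:
            raise ValueError("min_event_months must be >= 0")


#: colorectal rule: recurrence within 3 years vs recurrence-free >= 4 years,
#: recurrences within the first month excluded.
COLORECTAL_SCHEME = DichotomizationScheme(36.0, 48.0, 1.0)
#: breast rule: recurrence within 5 years vs recurrence-free >= 7 years.
BREAST_SCHEME = DichotomizationScheme(60.0, 84.0, 0.0)


@dataclass(frozen=True)
class LinearSignature:
    """A fitted scaled linear risk classifier."""

    genes: tuple[str, ...]
    scale_means: tuple[float, ...]
    scale_sds: tuple[float, ...]
    weights: tuple[float, ...]
    offset: float

    def __post_init__(self) -> None:
        k = len(self.genes)
        if not (len(self.scale_means) == len(self.scale_sds) == len(self.weights) == k):
            raise ValueError("genes, means, sds and weights must have equal length")
        if any(sd <= 0 for sd in self.scale_sds):
            raise ValueError("scaling standard deviations must be positive")


@dataclass(frozen=True)
class SignatureEvaluation:
    sensitivity: float
    specificity: float
    auc: float
    cohort_role: str = "training"

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "cohort_role": self.cohort_role,
        }


@dataclass(frozen=True)
class SearchEntry:
    """One signature that survived the filtration cascade."""

    genes: tuple[str, ...]
    signature: LinearSignature
    training: SignatureEvaluation
    filtrations: tuple[SignatureEvaluation, ...]
    mean_auc: float


def read_cohort(
    path,
    role: str = "training",
    *,
    status_column: str = "recurrence_status",
    time_column: str = "time_months",
    id_column: str = "patient_id",
) -> CohortDataset:
    """Read a cohort table: one row per patient, gene columns + status/time."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (id_column, status_column, time_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.set_index(id_column)
    genes = [c for c in df.columns if c not in (status_column, time_column)]
    return CohortDataset(
        expression=df[genes].astype(float),
        status=df[status_column].astype(str),
        time_months=df[time_column].astype(float),
        role=role,
    )


def dichotomize(cohort: CohortDataset, scheme: DichotomizationScheme) -> LabeledCohort:
    """Split a cohort into event/control classes, excluding the grey zone.

    Exclusion counts (unknown status, early events, grey zone) are recorded
    on the result.  Raises if either class comes out empty.
    """
    status, t = cohort.status, cohort.time_months
    unknown = status == UNKNOWN
    early = (status == RECURRED) & (t <= scheme.min_event_months)
    is_event = (
        (status == RECURRED)
        & (t > scheme.min_event_months)
        & (t <= scheme.event_horizon_months)
    )
    is_control = (status == RECURRENCE_FREE) & (t >= scheme.control_min_followup_months)
    keep = is_event | is_control
    grey = ~keep & ~unknown & ~early
    if int(is_event.sum()) == 0:
        raise ValueError("dichotomization produced an empty event class")
    if int(is_control.sum()) == 0:
        raise ValueError("dichotomization produced an empty control class")
    return LabeledCohort(
        expression=cohort.expression.loc[keep],
        event=is_event.loc[keep],
        role=cohort.role,
        exclusions={
            "unknown_status": int(unknown.sum()),
            "early_event": int(early.sum()),
            "grey_zone": int(grey.sum()),
        },
    )


def _check_genes(expression: pd.DataFrame, genes: Sequence[str]) -> None:
    missing = [g for g in genes if g not in expression.columns]
    if missing:
        raise ValueError(f"genes absent from the cohort: {missing}")


def fit_signature(
    training: LabeledCohort, genes: Sequence[str], cost: float = 1.0
) -> LinearSignature:
    """Fit the scaled linear-SVM classifier on the training cohort.

    Class weights are inversely proportional to class sizes (balanced
    hinge loss); scaling means/sds come from the training cohort only.
    """
    genes = tuple(genes)
    _check_genes(training.expression, genes)
    if training.n_events == 0 or training.n_controls == 0:
        raise ValueError("training cohort must contain both classes")
    x = training.expression.loc[:, genes].to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    zero = [g for g, sd in zip(genes, sds) if sd <= 0]
    if zero:
        raise ValueError(f"genes with zero training variance: {zero}")
    z = (x - means) / sds
    y = training.event.to_numpy(dtype=int)
    clf = SVC(kernel="linear", C=cost, class_weight="balanced")
    clf.fit(z, y)
    # decision_function = w·z + b, positive side = class 1 (event);
    # R = w·z − ρ with ρ = −b.
    weights = clf.coef_[0]
    rho = -float(clf.intercept_[0])
    return LinearSignature(
        genes=genes,
        scale_means=tuple(float(v) for v in means),
        scale_sds=tuple(float(v) for v in sds),
        weights=tuple(float(v) for v in weights),
        offset=rho,
    )


def risk_scores(sig: LinearSignature, expression: pd.DataFrame) -> pd.Series:
    """Continuous risk score R per patient (high risk where R >= 0)."""
    _check_genes(expression, sig.genes)
    x = expression.loc[:, list(sig.genes)].to_numpy(dtype=float)
    z = (x - np.asarray(sig.scale_means)) / np.asarray(sig.scale_sds)
    r = z @ np.asarray(sig.weights) - sig.offset
    return pd.Series(r, index=expression.index, name="risk_score")


def evaluate(sig: LinearSignature, cohort: LabeledCohort) -> SignatureEvaluation:
    """Sensitivity, specificity and tie-corrected AUC on a labeled cohort."""
    r = risk_scores(sig, cohort.expression).to_numpy()
    y = cohort.event.to_numpy(dtype=bool)
    high = r >= 0.0
    sensitivity = float(high[y].mean()) if y.any() else float("nan")
    specificity = float((~high[~y]).mean()) if (~y).any() else float("nan")
    if y.any() and (~y).any():
        if np.ptp(r) == 0:
            auc = 0.5  # all scores tied: the ROC is the diagonal
        else:
            auc = float(roc_auc_score(y, r))
    else:
        auc = float("nan")
    return SignatureEvaluation(sensitivity, specificity, auc, cohort.role)


def exhaustive_search(
    training: LabeledCohort,
    filtrations: Sequence[LabeledCohort],
    genes_universe: Iterable[str],
    set_size: int = 3,
    train_threshold: float = 0.6,
    filtration_threshold: float = 0.5,
    cost: float = 1.0,
) -> list[SearchEntry]:
    """Fit and filter every gene subset of the given size.

    A candidate is kept only if both sensitivity and specificity reach
    ``train_threshold`` on training and ``filtration_threshold`` on every
    filtration cohort.  Survivors are sorted by descending mean AUC over
    training + filtration cohorts (tie-break: lexicographic gene tuple).
    Subsets are enumerated in lexicographic order; the result does not
    depend on that order.
    """
    universe = sorted(set(genes_universe))
    if not universe:
        raise ValueError("empty gene universe")
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if not 0 < train_threshold < 1 or not 0 < filtration_threshold < 1:
        raise ValueError("thresholds must be fractions in (0, 1)")
    entries: list[SearchEntry] = []
    for genes in combinations(universe, set_size):
        try:
            sig = fit_signature(training, genes, cost=cost)
        except ValueError:
            continue  # e.g. zero-variance gene in this subset
        train_eval = evaluate(sig, training)
        if train_eval.sensitivity < train_threshold or train_eval.specificity < train_threshold:
            continue
        filt_evals = []
        passed = True
        for cohort in filtrations:
            ev = evaluate(sig, cohort)
            filt_evals.append(ev)
            if ev.sensitivity < filtration_threshold or ev.specificity < filtration_threshold:
                passed = False
                break
        if not passed:
            continue
        aucs = [train_eval.auc] + [ev.auc for ev in filt_evals]
        entries.append(
            SearchEntry(
                genes=genes,
                signature=sig,
                training=train_eval,
                filtrations=tuple(filt_evals),
                mean_auc=float(np.mean(aucs)),
            )
        )
    entries.sort(key=lambda e: (-e.mean_auc, e.genes))
    return entries


def km_logrank(
    time_a: Sequence[float],
    event_a: Sequence[bool],
    time_b: Sequence[float],
    event_b: Sequence[bool],
) -> tuple[float, dict]:
    """Two-tailed log-rank comparison of two survival samples.

    Returns the p-value and Kaplan–Meier curve coordinates (per-group step
    functions) ready for export/plotting.
    """
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, bool), np.asarray(event_b, bool)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both survival groups must be non-empty")
    result = logrank_test(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    curves = {}
    for name, t, e in (("group_a", time_a, event_a), ("group_b", time_b, event_b)):
        km = KaplanMeierFitter()
        km.fit(t, event_observed=e)
        sf = km.survival_function_
        curves[name] = {
            "time": [float(v) for v in sf.index],
            "survival": [float(v) for v in sf.iloc[:, 0]],
        }
    return float(result.p_value), curves


def cross_validate(
    training: LabeledCohort,
    genes: Sequence[str],
    folds: int = 3,
    cost: float = 1.0,
    seed: int = 0,
) -> list[SignatureEvaluation]:
    """Stratified k-fold cross-validation of one gene set on the training cohort.

    Each fold refits the scaler and the SVM on the in-fold patients only and
    evaluates on the held-out patients.  Fold assignment is seeded.
    """
    y = training.event.to_numpy(dtype=int)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds the number of patients ({n})")
    if folds == n:  # leave-one-out: stratification is vacuous
        splits = LeaveOneOut().split(np.zeros(n))
    elif min(training.n_events, training.n_controls) < folds:
        raise ValueError(
            f"smallest class ({min(training.n_events, training.n_controls)}) "
            f"is smaller than the number of folds ({folds})"
        )
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y)
    out: list[SignatureEvaluation] = []
    for train_idx, test_idx in splits:
        fold_train = LabeledCohort(
            expression=training.expression.iloc[train_idx],
            event=training.event.iloc[train_idx],
            role="training",
        )
        fold_test = LabeledCohort(
            expression=training.expression.iloc[test_idx],
            event=training.event.iloc[test_idx],
            role="cv_test",
        )
        sig = fit_signature(fold_train, genes, cost=cost)
        out.append(evaluate(sig, fold_test))
    return out
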