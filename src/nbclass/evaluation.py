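"""Evaluation metrics and the double nested cross-validation protocol.

Because ambiguous cell lines are excluded up front, every test sample is
truly resistant or sensitive, but regression-style predictors may still emit
an ambiguous call — so confusion matrices here are 2 (actual) x 3 (predicted)
with counts TS, FAS, FR / FS, FAR, TR. The balanced accuracy used throughout
is the 2x3 generalization

    BAC = 0.5 * TS/(TS+FAS+FR) + 0.5 * TR/(FS+FAR+TR)

which reduces to the usual mean of per-class recalls when no prediction is
ambiguous (FAS = FAR = 0, as for any hard classifier). The companion
balanced ambiguous rate 0.5*FAS/(TS+FAS+FR) + 0.5*FAR/(FS+FAR+TR) measures
how much probability mass a regression predictor leaves in the ambiguous
zone; BAC, the ambiguous rate and the balanced error always sum to one.

The protocol is a double nested stratified 5-fold CV: the inner CV tunes the
predictor's outer parameter (for the network classifier, the correlation
threshold) by balanced accuracy; the outer CV measures performance; the whole
procedure repeats with fresh partitions and metrics are averaged over folds
then repeats. Feature selection and all fitting happen strictly inside each
training portion.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from math import sqrt
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._utils import child_seed, logger
from .errors import InfeasibilityError, MetricError
from .labeling import AMBIGUOUS, CLASSES, RESISTANT, SENSITIVE, LabeledDataset
from .nbc import NBCModel


@dataclass(frozen=True)
class ConfusionMatrix23:
    """2 (actual) x 3 (predicted) confusion counts.

    ts/fas/fr: actual-sensitive predicted sensitive/ambiguous/resistant;
    fs/far/tr: actual-resistant predicted sensitive/ambiguous/resistant.
    """

    ts: int = 0
    fas: int = 0
    fr: int = 0
    fs: int = 0
    far: int = 0
    tr: int = 0

    def __post_init__(self) -> None:
        if min(self.ts, self.fas, self.fr, self.fs, self.far, self.tr) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def n_sensitive(self) -> int:
        return self.ts + self.fas + self.fr

    @property
    def n_resistant(self) -> int:
        return self.fs + self.far + self.tr

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix23":
        yt = np.asarray(y_true, dtype=object)
        yp = np.asarray(y_pred, dtype=object)
        if yt.shape != yp.shape:
            raise MetricError("y_true and y_pred must have equal length")
        sens = yt == SENSITIVE
        resi = yt == RESISTANT
        return cls(
            ts=int((sens & (yp == SENSITIVE)).sum()),
            fas=int((sens & (yp == AMBIGUOUS)).sum()),
            fr=int((sens & (yp == RESISTANT)).sum()),
            fs=int((resi & (yp == SENSITIVE)).sum()),
            far=int((resi & (yp == AMBIGUOUS)).sum()),
            tr=int((resi & (yp == RESISTANT)).sum()),
        )

    def __add__(self, other: "ConfusionMatrix23") -> "ConfusionMatrix23":
        return ConfusionMatrix23(
            self.ts + other.ts, self.fas + other.fas, self.fr + other.fr,
            self.fs + other.fs, self.far + other.far, self.tr + other.tr,
        )


def _check_rows(cm: ConfusionMatrix23) -> None:
    if cm.n_sensitive == 0 or cm.n_resistant == 0:
        raise MetricError("both actual classes must be non-empty")


def balanced_accuracy(cm: ConfusionMatrix23) -> float:
    """Class-balanced accuracy on the 2x3 confusion (Modified BAC)."""
    _check_rows(cm)
    return 0.5 * cm.ts / cm.n_sensitive + 0.5 * cm.tr / cm.n_resistant


def ambiguous_rate(cm: ConfusionMatrix23) -> float:
    """Balanced rate of predictions falling into the ambiguous zone."""
    _check_rows(cm)
    return 0.5 * cm.fas / cm.n_sensitive + 0.5 * cm.far / cm.n_resistant


def mcc(cm: ConfusionMatrix23) -> float:
    """Matthews correlation on the 2x2 part; ambiguous columns are dropped
    with a warning (only hard classifiers report MCC cleanly)."""
    if cm.fas or cm.far:
        logger.warning(
            "MCC on a 2x3 confusion: dropping %d ambiguous predictions",
            cm.fas + cm.far,
        )
    num = cm.ts * cm.tr - cm.fs * cm.fr
    den = (cm.ts + cm.fs) * (cm.ts + cm.fr) * (cm.tr + cm.fs) * (cm.tr + cm.fr)
    if den == 0:
        return 0.0
    return num / sqrt(den)


def roc_auc(scores, labels) -> float:
    """AUC of a decision score where larger means more sensitive.

    Rank-based (ties contribute one half); for the network classifier the
    canonical score is mse_resistant − mse_sensitive.
    """
    lab = np.asarray(labels, dtype=object)
    if not ((lab == SENSITIVE).any() and (lab == RESISTANT).any()):
        raise MetricError("ROC AUC needs both classes present")
    return float(roc_auc_score((lab == SENSITIVE).astype(int), np.asarray(scores, float)))


@dataclass
class EvaluationReport:
    """Repeat-averaged metrics from the nested CV protocol."""

    drug: str
    predictor: str
    bac: float
    bac_sd: float
    mcc: float
    modified_bac: float
    ambiguous_rate: float
    auc: float | None
    per_repeat: pd.DataFrame
    n_repeats: int
    n_folds: int
    seed: int
    chosen_params: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("bac", self.bac, self.bac_sd),
            ("mcc", self.mcc, float(self.per_repeat["mcc"].std(ddof=0))),
            ("modified_bac", self.modified_bac, self.bac_sd),
            ("ambiguous_rate", self.ambiguous_rate,
             float(self.per_repeat["ambiguous_rate"].std(ddof=0))),
        ]
        if self.auc is not None:
            rows.append(("auc", self.auc, float(self.per_repeat["auc"].std(ddof=0))))
        return pd.DataFrame(
            [
                {
                    "drug": self.drug, "predictor": self.predictor, "metric": m,
                    "mean": v, "sd": s, "n_repeats": self.n_repeats, "seed": self.seed,
                }
                for m, v, s in rows
            ]
        )

    def to_json_dict(self) -> dict:
        return {
            "drug": self.drug,
            "predictor": self.predictor,
            "bac": self.bac,
            "bac_sd": self.bac_sd,
            "mcc": self.mcc,
            "modified_bac": self.modified_bac,
            "ambiguous_rate": self.ambiguous_rate,
            "auc": self.auc,
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "per_repeat": self.per_repeat.to_dict(orient="list"),
        }


@dataclass(frozen=True)
class PredictorSpec:
    """A pluggable predictor: a factory over an outer tuning grid.

    ``factory(param)`` returns a fresh unfitted estimator with fit/predict
    (and optionally decision_scores). A single-point grid disables tuning.
    """

    name: str
    factory: Callable[[Any], Any]
    grid: Sequence[Any]


def _stratified_splits(y: np.ndarray, n_splits: int, seed: int):
    counts = [int((y == c).sum()) for c in CLASSES]
    if min(counts) < n_splits:
        raise InfeasibilityError(
            f"class counts {dict(zip(CLASSES, counts))} cannot be stratified "
            f"into {n_splits} folds"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y.astype(str)))


def _fold_metrics(est, X_te: pd.DataFrame, y_te: np.ndarray) -> dict:
    y_pred = est.predict(X_te)
    cm = ConfusionMatrix23.from_predictions(y_te, y_pred)
    out = {
        "bac": balanced_accuracy(cm),
        "ambiguous_rate": ambiguous_rate(cm),
        "mcc": mcc(cm),
    }
    if hasattr(est, "decision_scores"):
        out["auc"] = roc_auc(est.decision_scores(X_te), y_te)
    return out


def nested_cv(
    dataset: LabeledDataset | pd.DataFrame,
    labels: pd.Series | None = None,
    predictor_spec: PredictorSpec = None,
    outer_folds: int = 5,
    inner_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    drug: str = "",
) -> EvaluationReport:
    """Double nested stratified CV with repeats.

    Per repeat, an outer stratified split measures performance while an inner
    stratified split on each training portion tunes the predictor's grid
    parameter by balanced accuracy (ties keep the earliest grid entry). Each
    estimator is fit exclusively on training-portion rows, so feature
    selection and network construction never see test samples. Raises
    :class:`InfeasibilityError` when a stratified split cannot keep both
    classes in every fold.
    """
    if isinstance(dataset, LabeledDataset):
        X, y = dataset.features, dataset.labels
    else:
        X, y = dataset, labels
    y_arr = np.asarray(y, dtype=object)

    repeat_rows = []
    chosen_params: list = []
    for r in range(n_repeats):
        outer = _stratified_splits(y_arr, outer_folds, child_seed(seed, r, 0))
        fold_rows = []
        for f, (tr, te) in enumerate(outer):
            X_tr, y_tr = X.iloc[tr], y_arr[tr]
            if len(predictor_spec.grid) > 1:
                inner = _stratified_splits(y_tr, inner_folds, child_seed(seed, r, 1 + f))
                best_param, best_bac = None, -np.inf
                for param in predictor_spec.grid:
                    bacs = []
                    for itr, iva in inner:
                        est = predictor_spec.factory(param)
                        est.fit(X_tr.iloc[itr], y_tr[itr])
                        cm = ConfusionMatrix23.from_predictions(
                            y_tr[iva], est.predict(X_tr.iloc[iva])
                        )
                        bacs.append(balanced_accuracy(cm))
                    mean_bac = float(np.mean(bacs))
                    if mean_bac > best_bac:  # strict: earliest grid entry wins ties
                        best_param, best_bac = param, mean_bac
            else:
                best_param = predictor_spec.grid[0]
            chosen_params.append(best_param)
            est = predictor_spec.factory(best_param)
            est.fit(X_tr, y_tr)
            fold_rows.append(_fold_metrics(est, X.iloc[te], y_arr[te]))
        fold_df = pd.DataFrame(fold_rows)
        repeat_rows.append(fold_df.mean().to_dict())

    per_repeat = pd.DataFrame(repeat_rows)
    has_auc = "auc" in per_repeat.columns
    return EvaluationReport(
        drug=drug,
        predictor=predictor_spec.name,
        bac=float(per_repeat["bac"].mean()),
        bac_sd=float(per_repeat["bac"].std(ddof=0)),
        mcc=float(per_repeat["mcc"].mean()),
        modified_bac=float(per_repeat["bac"].mean()),
        ambiguous_rate=float(per_repeat["ambiguous_rate"].mean()),
        auc=float(per_repeat["auc"].mean()) if has_auc else None,
        per_repeat=per_repeat,
        n_repeats=n_repeats,
        n_folds=outer_folds,
        seed=seed,
        chosen_params=chosen_params,
    )


def stratified_subset_eval(
    dataset: LabeledDataset,
    grouping: pd.Series,
    predictor_spec: PredictorSpec,
    drug: str = "",
    **cv_kwargs,
) -> dict[str, EvaluationReport | str]:
    """Nested CV per cancer-type subset, with the feasibility filter.

    Subsets whose stratified splits would lose a class (no resistant or no
    sensitive cell lines in some fold) are reported as ``"insufficient"``
    instead of a report.
    """
    groups = grouping.loc[dataset.features.index]
    out: dict[str, EvaluationReport | str] = {}
    for group in sorted(groups.unique()):
        mask = (groups == group).to_numpy()
        sub = LabeledDataset(
            features=dataset.features.loc[mask],
            labels=dataset.labels.loc[mask],
            dropped_ambiguous=0,
        )
        try:
            out[group] = nested_cv(
                sub, predictor_spec=predictor_spec, drug=drug, **cv_kwargs
            )
        except InfeasibilityError:
            out[group] = "insufficient"
    return out


@dataclass(frozen=True)
class ContributionProfile:
    """Per-gene prediction success rates over a test set."""

    rates: pd.DataFrame  # index: gene; columns: prediction_success_rate, n_test_samples

    def to_frame(self) -> pd.DataFrame:
        return self.rates.reset_index(names="gene")


def prediction_success_rate(
    model: NBCModel, X_test: pd.DataFrame, y_test
) -> ContributionProfile:
    """Fraction of test samples each gene helps classify correctly.

    A gene contributes on a sample when the squared reconstruction error of
    the sample's *true* class network is strictly smaller than the other
    class's (for a resistant sample, eps_r < eps_s).
    """
    y_arr = np.asarray(y_test, dtype=object)
    if len(X_test) == 0:
        raise MetricError("need at least one test sample")
    genes = list(model.genes)
    counts = np.zeros(len(genes))
    sub = X_test[genes].to_numpy()
    for row, true_cls in zip(sub, y_arr):
        res = model.classify(row)
        eps_s = res.per_gene_errors["eps_sensitive"].to_numpy()
        eps_r = res.per_gene_errors["eps_resistant"].to_numpy()
        if true_cls == RESISTANT:
            counts += eps_r < eps_s
        else:
            counts += eps_s < eps_r
    rates = pd.DataFrame(
        {
            "prediction_success_rate": counts / len(X_test),
            "n_test_samples": len(X_test),
        },
        index=pd.Index(genes, name="gene"),
    )
    return ContributionProfile(rates)


def correlation_threshold_profile(
    dataset: LabeledDataset | pd.DataFrame,
    labels: pd.Series | None = None,
    thresholds: Sequence[float] = (),
    factory: Callable[[float], Any] = None,
    folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Repeat-averaged CV balanced accuracy at each fixed threshold.

    Plain (non-nested) stratified CV per threshold — the protocol for tracing
    how accuracy responds to network density.
    """
    out = {}
    for thr in thresholds:
        spec = PredictorSpec(name=f"thr={thr}", factory=factory, grid=[thr])
        rep = nested_cv(
            dataset, labels, predictor_spec=spec, outer_folds=folds,
            inner_folds=folds, n_repeats=n_repeats, seed=seed,
        )
        out[thr] = rep.bac
    return pd.Series(out, name="bac")
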