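"""Resistant / ambiguous / sensitive labeling of cell lines from EC50 values.

A drug response is summarized by its EC50 in µM. On the −log10 molar scale
(score = 6 − log10(EC50 µM)) a pair of cutoffs partitions cell lines into
three zones:

* score > sensitive cutoff  → **sensitive**
* score < resistant cutoff  → **resistant**
* otherwise                 → **ambiguous** (excluded from training/testing)

Clinical cutoffs derive from the average peak plasma concentration Cmax at
standard dosing::

    resistant = −log10(Cmax · 1.5) + 6      sensitive = −log10(Cmax / 1.5) + 6

so every unclamped clinical pair is separated by exactly 2·log10(1.5). When
no reliable Cmax exists, statistical cutoffs use the mean µ and SD σ of the
drug's EC50 distribution across cell lines: −log10 of (µ ± 0.3σ) converted
to molar. An optional floor clamp (default 5.0, i.e. 10 µM) reproduces
published cutoff tables whose resistant cutoffs bottom out at 5.000.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io_formats import ExpressionMatrix

RESISTANT = "resistant"
AMBIGUOUS = "ambiguous"
SENSITIVE = "sensitive"
CLASSES = (RESISTANT, SENSITIVE)

#: separation of every unclamped clinical cutoff pair, in −log10 units
CLINICAL_GAP = 2 * math.log10(1.5)

#: −log10 molar floor applied when clamping is on (10 µM, a typical max dose)
DEFAULT_CLAMP_FLOOR = 5.0


@dataclass(frozen=True)
class CutoffPair:
    """(resistant, sensitive) thresholds on the −log10 molar scale."""

    resistant: float
    sensitive: float
    source: str  # "clinical" | "statistical"
    cmax_um: float | None = None
    mu_um: float | None = None
    sigma_um: float | None = None

    def __post_init__(self) -> None:
        if self.resistant > self.sensitive + 1e-12:
            raise ValidationError(
                f"resistant cutoff {self.resistant} exceeds sensitive cutoff "
                f"{self.sensitive}"
            )


@dataclass(frozen=True)
class LabeledDataset:
    """Non-ambiguous samples ready for model training.

    ``features`` is samples x genes; ``labels`` holds per-sample class in
    {resistant, sensitive}; ambiguous cell lines are already excluded.
    """

    features: pd.DataFrame
    labels: pd.Series
    dropped_ambiguous: int


def neg_log10_molar(ec50_um) -> np.ndarray:
    """Convert EC50 in µM to the −log10 molar score: 6 − log10(EC50)."""
    arr = np.asarray(ec50_um, dtype=float)
    if (arr <= 0).any():
        raise DomainError("EC50 values must be strictly positive")
    return 6.0 - np.log10(arr)


def clinical_cutoffs(
    cmax_um: float, clamp_floor: float | None = DEFAULT_CLAMP_FLOOR
) -> CutoffPair:
    """Cutoff pair from the clinical peak plasma concentration (µM).

    With ``clamp_floor`` set (default 5.0) each cutoff is raised to at least
    that value; pass ``None`` for the raw formulas.
    """
    if cmax_um <= 0:
        raise DomainError(f"Cmax must be positive, got {cmax_um}")
    resistant = -math.log10(cmax_um * 1.5) + 6.0
    sensitive = -math.log10(cmax_um / 1.5) + 6.0
    if clamp_floor is not None:
        resistant = max(resistant, clamp_floor)
        sensitive = max(sensitive, clamp_floor)
    return CutoffPair(resistant, sensitive, source="clinical", cmax_um=cmax_um)


def statistical_cutoffs(
    ec50_um_values: Sequence[float],
    ddof: int = 1,
    on_neglog_scale: bool = False,
) -> CutoffPair:
    """Cutoff pair from the EC50 distribution: −log10 of (µ ± 0.3σ) molar.

    ``ddof=1`` uses the sample SD (default); ``ddof=0`` the population SD.
    With ``on_neglog_scale`` µ and σ are instead computed on the −log10 molar
    scores and the cutoffs are µ ∓ 0.3σ directly (alternative reading).
    """
    arr = np.asarray(ec50_um_values, dtype=float)
    if arr.size < 2:
        raise DomainError("need at least 2 EC50 values for statistical cutoffs")
    if (arr <= 0).any():
        raise DomainError("EC50 values must be strictly positive")
    if on_neglog_scale:
        scores = neg_log10_molar(arr)
        mu, sigma = float(scores.mean()), float(scores.std(ddof=ddof))
        return CutoffPair(
            mu - 0.3 * sigma, mu + 0.3 * sigma, source="statistical"
        )
    mu, sigma = float(arr.mean()), float(arr.std(ddof=ddof))
    lo = mu - 0.3 * sigma
    if lo <= 0:
        raise DomainError(
            f"mu - 0.3*sigma = {lo:.4g} <= 0: statistical cutoff undefined"
        )
    resistant = 6.0 - math.log10(mu + 0.3 * sigma)
    sensitive = 6.0 - math.log10(lo)
    return CutoffPair(
        resistant, sensitive, source="statistical", mu_um=mu, sigma_um=sigma
    )


def assign_labels(ec50_um, cutoffs: CutoffPair):
    """Assign each cell line to resistant / ambiguous / sensitive.

    Inequalities are strict: a score exactly equal to a cutoff is ambiguous.
    Returns a Series if given one, else an ndarray of class strings.
    """
    index = ec50_um.index if isinstance(ec50_um, pd.Series) else None
    scores = neg_log10_molar(ec50_um)
    out = np.full(scores.shape, AMBIGUOUS, dtype=object)
    out[scores > cutoffs.sensitive] = SENSITIVE
    out[scores < cutoffs.resistant] = RESISTANT
    if index is not None:
        return pd.Series(out, index=index, name="label")
    return out


def label_dataset(
    expr: ExpressionMatrix, ec50_um: pd.Series, cutoffs: CutoffPair
) -> LabeledDataset:
    """Label aligned cell lines and drop the ambiguous ones.

    Raises :class:`ValidationError` if either class ends up empty — no model
    can be trained on a single class.
    """
    labels = assign_labels(ec50_um, cutoffs)
    keep = labels != AMBIGUOUS
    kept = labels[keep]
    for cls in CLASSES:
        if not (kept == cls).any():
            raise ValidationError(
                f"no {cls} cell lines remain after applying cutoffs "
                f"({cutoffs.resistant:.3f}, {cutoffs.sensitive:.3f})"
            )
    features = expr.data[list(kept.index)].T
    return LabeledDataset(
        features=features, labels=kept, dropped_ambiguous=int((~keep).sum())
    )


def filter_balanced_drugs(
    label_sets: Mapping[str, Sequence[str]], min_per_class: int
) -> list[str]:
    """Drugs whose class balance supports training.

    A drug is retained iff both classes have at least ``min_per_class``
    non-ambiguous cell lines; heavily one-sided drugs are excluded.
    """
    if min_per_class < 1:
        raise DomainError("min_per_class must be >= 1")
    retained = []
    for drug, labels in label_sets.items():
        arr = np.asarray(labels, dtype=object)
        if all(int((arr == cls).sum()) >= min_per_class for cls in CLASSES):
            retained.append(drug)
    return retained


def cutoffs_from_metadata(
    meta: pd.DataFrame, clamp_floor: float | None = DEFAULT_CLAMP_FLOOR
) -> dict[str, CutoffPair]:
    """Build per-drug cutoff pairs from a drug-metadata table.

    Precomputed cutoff columns win over Cmax when both are present.
    """
    out: dict[str, CutoffPair] = {}
    has_pair = {"resistant_cutoff", "sensitive_cutoff"}.issubset(meta.columns)
    for _, row in meta.iterrows():
        drug = row["drug"]
        if has_pair and pd.notna(row.get("resistant_cutoff")):
            out[drug] = CutoffPair(
                float(row["resistant_cutoff"]),
                float(row["sensitive_cutoff"]),
                source="clinical",
            )
        elif "cmax_um" in meta.columns and pd.notna(row.get("cmax_um")):
            out[drug] = clinical_cutoffs(float(row["cmax_um"]), clamp_floor)
    return out
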