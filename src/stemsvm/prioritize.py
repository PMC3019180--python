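"""Candidate-list prioritization: predicted-positive fractions, the
signal-to-noise enrichment ratio, persistent false positives across
configurations, and the positive-vs-negative fraction comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stemsvm.classify import KernelModel, NEGATIVE_LABEL, POSITIVE_LABEL
from stemsvm.features import FeatureMatrix


@dataclass(frozen=True)
class PrioritizationResult:
    """Predicted-positive percentages per list and their ratio.

    ``ratio`` is None with ``infinite=True`` when no gene in the
    negative list is predicted positive.
    """

    pos_fraction: float  # percent
    neg_fraction: float  # percent
    ratio: float | None
    infinite: bool
    predictions: pd.DataFrame  # gene_id, list, score, label


def signal_to_noise(
    model: KernelModel,
    positive_candidates: Sequence[str],
    negative_candidates: Sequence[str],
    features: FeatureMatrix,
    training_ids: Sequence[str] = (),
) -> PrioritizationResult:
    """Classify both candidate lists and form the enrichment ratio."""
    pos = list(positive_candidates)
    neg = list(negative_candidates)
    if not pos or not neg:
        raise ValueError("both candidate lists must be non-empty")
    missing = (set(pos) | set(neg)) - set(features.gene_ids)
    if missing:
        raise ValueError(f"candidates absent from the feature matrix: {sorted(missing)[:5]}")
    seen = (set(pos) | set(neg)) & set(training_ids)
    if seen:
        warnings.warn(
            f"{len(seen)} candidate gene(s) overlap the training set; "
            "they were seen by the classifier during training"
        )
    rows = []
    fractions = {}
    for list_name, ids in (("positive", pos), ("negative", neg)):
        X = features.values.loc[ids].to_numpy()
        scores = model.decision_function(X)
        calls = scores > 0
        fractions[list_name] = 100.0 * np.mean(calls)
        for gid, s, c in zip(ids, scores, calls):
            rows.append(
                (gid, list_name, float(s), POSITIVE_LABEL if c else NEGATIVE_LABEL)
            )
    pred = pd.DataFrame(rows, columns=["gene_id", "list", "score", "label"])
    if fractions["negative"] == 0.0:
        return PrioritizationResult(
            fractions["positive"], 0.0, None, True, pred
        )
    return PrioritizationResult(
        fractions["positive"],
        fractions["negative"],
        fractions["positive"] / fractions["negative"],
        False,
        pred,
    )


def consistent_misclassified(
    predictions_by_config: Mapping[str, Mapping[str, bool]],
    labels: Mapping[str, str] | None = None,
) -> list[str]:
    """Genes flagged in every configuration.

    Without labels: genes predicted positive everywhere. With labels
    ('positive'/'negative'): genes whose prediction contradicts their
    label in every configuration.
    """
    if len(predictions_by_config) < 2:
        raise ValueError("need at least 2 configurations")
    configs = list(predictions_by_config.values())
    universe = set(configs[0])
    for preds in configs[1:]:
        if set(preds) != universe:
            raise ValueError("gene universes differ between configurations")

    def flagged(gene: str, called_positive: bool) -> bool:
        if labels is None:
            return called_positive
        return called_positive != (labels[gene] == "positive")

    return sorted(
        g for g in universe if all(flagged(g, preds[g]) for preds in configs)
    )


def compare_ratio_groups(
    pos_fractions: Sequence[float],
    neg_fractions: Sequence[float],
    welch: bool = True,
) -> tuple[float, float]:
    """Two-sample t statistic and two-tailed p (Welch by default)."""
    a = np.asarray(pos_fractions, dtype=float)
    b = np.asarray(neg_fractions, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
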