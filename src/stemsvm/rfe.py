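"""SVM recursive feature elimination.

Each round trains the SVM on the remaining features and removes the
ones contributing least to the squared margin. The criterion is the
kernel-space margin change |W^2(alpha) - W^2_(-j)(alpha)| with
W^2(alpha) = sum_ik alpha_i alpha_k y_i y_k K(x_i, x_k), where K_(-j)
is the Gram matrix recomputed with feature j removed (the trained alpha
is reused). For the linear kernel this reduces exactly to the primal
weight magnitude w_j^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from stemsvm.classify import train_svm
from stemsvm.evaluate import fisher_overlap
from stemsvm.kernels import KernelSpec


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered best-discriminating first, with the per-round
    elimination criterion for each feature."""

    features: tuple[str, ...]
    criteria: pd.DataFrame  # round, feature, criterion (NaN for final survivor)

    def top_k(self, k: int = 20) -> list[str]:
        return list(self.features[:k])


def _criterion_values(
    X: np.ndarray, v: np.ndarray, K: np.ndarray, spec: KernelSpec
) -> np.ndarray:
    """|W^2 - W^2_(-j)| for every column j of X, given dual coefs v."""
    base = float(v @ K @ v)
    p = X.shape[1]
    out = np.empty(p)
    if spec.family == "linear":
        # K_(-j) = K - x_j x_j^T  =>  delta = (v . x_j)^2 = w_j^2
        w = X.T @ v
        return w**2
    if spec.family == "polynomial":
        G = X @ X.T
        for j in range(p):
            xj = X[:, j]
            Kj = (G - np.outer(xj, xj) + 1.0) ** spec.degree
            out[j] = abs(base - float(v @ Kj @ v))
        return out
    if spec.family == "rbf":
        two_sq = 2.0 * spec.sigma**2
        for j in range(p):
            xj = X[:, j]
            Dj = (xj[:, None] - xj[None, :]) ** 2
            Kj = K * np.exp(Dj / two_sq)
            out[j] = abs(base - float(v @ Kj @ v))
        return out
    raise ValueError(f"RFE does not support kernel family {spec.family!r}")


def _gram(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.family == "linear":
        return X @ X.T
    if spec.family == "polynomial":
        return (X @ X.T + 1.0) ** spec.degree
    return np.exp(-cdist(X, X, "sqeuclidean") / (2.0 * spec.sigma**2))


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    feature_names=None,
    C: float = 1.0,
    step: int = 1,
) -> FeatureRanking:
    """Rank all features by recursive elimination.

    Hyperparameters are frozen across rounds. Ties in the criterion are
    broken by eliminating the lower column index first. ``step`` features
    are removed per round; a final short round removes all survivors
    ranked by their criterion.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    if step < 1:
        raise ValueError("step must be >= 1")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    feature_names = list(feature_names)
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")

    remaining = list(range(p))
    eliminated: list[int] = []  # worst first
    log_rows = []
    rnd = 0
    while remaining:
        rnd += 1
        if len(remaining) == 1:
            j = remaining.pop()
            eliminated.append(j)
            log_rows.append((rnd, feature_names[j], np.nan))
            break
        Xr = X[:, remaining]
        K = _gram(Xr, spec)
        model = train_svm(K, y, C=C, validate=False)
        crit = _criterion_values(Xr, model.dual_coef, K, spec)
        # stable argsort: ties resolved toward the lower column index
        order = np.argsort(crit, kind="stable")
        n_drop = min(step, len(remaining)) if step < len(remaining) else len(remaining)
        for pos in order[:n_drop]:
            j = remaining[pos]
            log_rows.append((rnd, feature_names[j], float(crit[pos])))
        dropped = {remaining[pos] for pos in order[:n_drop]}
        eliminated.extend(remaining[pos] for pos in order[:n_drop])
        remaining = [j for j in remaining if j not in dropped]

    ranking = tuple(feature_names[j] for j in reversed(eliminated))
    criteria = pd.DataFrame(log_rows, columns=["round", "feature", "criterion"])
    return FeatureRanking(features=ranking, criteria=criteria)


def ranking_overlap(
    rankA: FeatureRanking | list[str],
    rankB: FeatureRanking | list[str],
    k: int = 20,
    universe: int | None = None,
) -> tuple[int, float]:
    """Top-k overlap of two rankings and its Fisher's-exact enrichment p."""
    fa = list(rankA.features if isinstance(rankA, FeatureRanking) else rankA)
    fb = list(rankB.features if isinstance(rankB, FeatureRanking) else rankB)
    for name, feats in (("A", fa), ("B", fb)):
        if len(set(feats)) != len(feats):
            raise ValueError(f"ranking {name} contains duplicated features")
    if universe is None:
        universe = len(fa)
    if k > universe:
        raise ValueError("k exceeds the feature universe")
    top_a, top_b = set(fa[:k]), set(fb[:k])
    overlap = len(top_a & top_b)
    return overlap, fisher_overlap(sorted(top_a), sorted(top_b), universe)
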