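"""SVM training on precomputed Gram matrices, plus comparison baselines.

The dual solver is scikit-learn's SVC with a precomputed kernel, so any
Gram matrix — including the F1-weighted two-kernel combination — can be
used directly. Baselines: pooled-covariance LDA, an entropy-split
decision tree, a small feed-forward neural network (5 hidden units,
accuracy averaged over repeated random initializations), and the
ES/EB fold-change rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from stemsvm.kernels import KernelSpec, check_gram, compute_kernel, weighted_kernel

POSITIVE_LABEL = "MSMG"
NEGATIVE_LABEL = "not-MSMG"


def _spec_to_dict(spec: KernelSpec) -> dict:
    return {
        "family": spec.family,
        "degree": spec.degree,
        "sigma": spec.sigma,
        "components": [_spec_to_dict(c) for c in spec.components],
        "weights": list(spec.weights),
    }


def _spec_from_dict(d: dict) -> KernelSpec:
    return KernelSpec(
        family=d["family"],
        degree=d.get("degree"),
        sigma=d.get("sigma"),
        components=tuple(_spec_from_dict(c) for c in d.get("components", [])),
        weights=tuple(d.get("weights", [])),
    )


@dataclass(frozen=True)
class TrainedSVM:
    """Soft-margin dual solution on a precomputed kernel.

    ``dual_coef`` holds alpha_i * y_i for every training gene (zero for
    non-support vectors), so |dual_coef_i| <= C.
    """

    gene_ids: tuple[str, ...]
    dual_coef: np.ndarray
    bias: float
    C: float
    spec: KernelSpec | None = None

    def decision(self, K_test: np.ndarray) -> np.ndarray:
        """Signed scores for rows of K_test (test x training genes)."""
        K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
        if K_test.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"K_test has {K_test.shape[1]} columns, expected "
                f"{len(self.gene_ids)} (training gene order)"
            )
        return K_test @ self.dual_coef + self.bias

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "gene_ids": list(self.gene_ids),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "C": self.C,
            "spec": _spec_to_dict(self.spec) if self.spec else None,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedSVM":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            spec=_spec_from_dict(d["spec"]) if d.get("spec") else None,
        )


def train_svm(
    K: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    gene_ids=None,
    spec: KernelSpec | None = None,
    validate: bool = True,
) -> TrainedSVM:
    """Fit the soft-margin SVM dual on a precomputed Gram matrix.

    y must contain both classes, coded as +1/-1.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes, coded +1/-1")
    if C <= 0:
        raise ValueError("C must be > 0")
    if validate:
        check_gram(K)
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(K, y)
    dual = np.zeros(len(y))
    dual[svc.support_] = svc.dual_coef_[0]
    if gene_ids is None:
        gene_ids = tuple(f"i{i}" for i in range(len(y)))
    return TrainedSVM(
        gene_ids=tuple(gene_ids),
        dual_coef=dual,
        bias=float(svc.intercept_[0]),
        C=float(C),
        spec=spec,
    )


def predict(
    model: TrainedSVM, K_test: np.ndarray, gene_ids=None, threshold: float = 0.0
) -> pd.DataFrame:
    """Score test genes against the trained model; label by sign."""
    K_test = np.asarray(K_test, dtype=float)
    if K_test.size == 0:
        return pd.DataFrame(columns=["gene_id", "score", "label"])
    scores = model.decision(K_test)
    if gene_ids is None:
        gene_ids = [f"t{i}" for i in range(len(scores))]
    labels = [POSITIVE_LABEL if s > threshold else NEGATIVE_LABEL for s in scores]
    return pd.DataFrame({"gene_id": list(gene_ids), "score": scores, "label": labels})


@dataclass
class KernelModel:
    """Feature-space classifier: one or more kernel blocks over columns.

    blocks: list of (column indices, KernelSpec, weight). A plain
    single-kernel model is one block with weight 1; the weighted
    two-kernel combination is two blocks with F1 weights.
    """

    blocks: list[tuple[np.ndarray, KernelSpec, float]]
    C: float = 1.0
    X_train: np.ndarray | None = None
    svm: TrainedSVM | None = None

    def gram(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        K = None
        for idx, spec, w in self.blocks:
            Kb = w * compute_kernel(Xa[:, idx], Xb[:, idx], spec)
            K = Kb if K is None else weighted_kernel(K, Kb, 1.0, 1.0)
        return K

    def fit(self, X: np.ndarray, y: np.ndarray, gene_ids=None) -> "KernelModel":
        X = np.asarray(X, dtype=float)
        self.X_train = X
        self.svm = train_svm(
            self.gram(X, X), y, C=self.C, gene_ids=gene_ids, validate=False
        )
        return self

    def decision_function(self, X_new: np.ndarray) -> np.ndarray:
        if self.svm is None:
            raise RuntimeError("model is not fitted")
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return self.svm.decision(self.gram(X_new, self.X_train))

    def predict_positive(self, X_new: np.ndarray, threshold: float = 0.0) -> np.ndarray:
        return self.decision_function(X_new) > threshold


def fold_change_classifier(
    es_expr: np.ndarray, eb_expr: np.ndarray, gene_ids=None
) -> pd.DataFrame:
    """Call a gene positive iff its ES/EB expression ratio exceeds 1."""
    es = np.asarray(es_expr, dtype=float)
    eb = np.asarray(eb_expr, dtype=float)
    if np.any(eb <= 0):
        raise ValueError("EB expression must be strictly positive")
    ratio = es / eb
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(ratio))]
    labels = [POSITIVE_LABEL if r > 1.0 else NEGATIVE_LABEL for r in ratio]
    return pd.DataFrame({"gene_id": list(gene_ids), "score": ratio, "label": labels})


def _loocv_accuracy(make_clf, X: np.ndarray, y: np.ndarray) -> float:
    correct = 0
    n = len(y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = make_clf()
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def baseline_classify(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    ann_runs: int = 30,
    seed: int = 0,
) -> float:
    """LOOCV accuracy for one of the comparison baselines.

    lda: pooled-covariance linear discriminant (ridge-regularized
    fallback on singular covariance). dtree: entropy-criterion tree.
    ann: feed-forward net with one 5-unit hidden layer; accuracy is the
    mean over ``ann_runs`` random initializations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    for cls in np.unique(y):
        if np.sum(y == cls) < 2:
            raise ValueError("need at least 2 genes per class")
    if method == "lda":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", UserWarning)
                return _loocv_accuracy(
                    lambda: LinearDiscriminantAnalysis(solver="svd"), X, y
                )
        except (np.linalg.LinAlgError, UserWarning):
            warnings.warn("singular covariance; using ridge-regularized LDA")
            return _loocv_accuracy(
                lambda: LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
                X,
                y,
            )
    if method == "dtree":
        return _loocv_accuracy(
            lambda: DecisionTreeClassifier(criterion="entropy", random_state=seed),
            X,
            y,
        )
    if method == "ann":
        accs = []
        for r in range(ann_runs):
            accs.append(
                _loocv_accuracy(
                    lambda: MLPClassifier(
                        hidden_layer_sizes=(5,),
                        solver="lbfgs",
                        max_iter=2000,
                        random_state=seed + r,
                    ),
                    X,
                    y,
                )
            )
        return float(np.mean(accs))
    raise ValueError(f"unknown baseline method {method!r}")
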