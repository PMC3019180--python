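"""Gram-matrix computation: linear, polynomial, Gaussian RBF, and the
F1-weighted two-kernel combination, plus RBF width selection helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from stemsvm import io

FAMILIES = ("linear", "polynomial", "rbf", "weighted")

SYMMETRY_TOL = 1e-10
PSD_TOL_FACTOR = 1e-8  # min eigenvalue >= -factor * trace


class KernelParameterError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus exactly its own parameters.

    linear: no parameters. polynomial: degree (default 3).
    rbf: sigma > 0 (gamma = 1 / (2 sigma^2) exposed as an alias).
    weighted: two component specs and non-negative weights.
    """

    family: str
    degree: int | None = None
    sigma: float | None = None
    components: tuple["KernelSpec", ...] = field(default=())
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise KernelParameterError(f"unknown kernel family {self.family!r}")
        if self.family == "linear":
            if self.degree is not None or self.sigma is not None or self.components:
                raise KernelParameterError("linear kernel takes no parameters")
        elif self.family == "polynomial":
            object.__setattr__(self, "degree", 3 if self.degree is None else self.degree)
            if self.sigma is not None or self.components:
                raise KernelParameterError("polynomial kernel takes only a degree")
            if self.degree < 1:
                raise KernelParameterError("degree must be >= 1")
        elif self.family == "rbf":
            if self.degree is not None or self.components:
                raise KernelParameterError("rbf kernel takes only sigma")
            if self.sigma is None or self.sigma <= 0:
                raise KernelParameterError("rbf kernel requires sigma > 0")
        else:  # weighted
            if len(self.components) != 2 or len(self.weights) != 2:
                raise KernelParameterError(
                    "weighted kernel requires two components and two weights"
                )
            if any(w < 0 for w in self.weights):
                raise KernelParameterError("weights must be non-negative")

    @property
    def gamma(self) -> float:
        if self.family != "rbf":
            raise KernelParameterError("gamma is defined only for rbf kernels")
        return 1.0 / (2.0 * self.sigma**2)

    @classmethod
    def from_gamma(cls, gamma: float) -> "KernelSpec":
        if gamma <= 0:
            raise KernelParameterError("gamma must be > 0")
        return cls("rbf", sigma=float(1.0 / np.sqrt(2.0 * gamma)))

    def label(self) -> str:
        if self.family == "rbf":
            return f"rbf(sigma={self.sigma:.4g})"
        if self.family == "polynomial":
            return f"poly(d={self.degree})"
        if self.family == "weighted":
            return "weighted(" + ", ".join(c.label() for c in self.components) + ")"
        return "linear"


def compute_kernel(Xa: np.ndarray, Xb: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel values between the rows of Xa and the rows of Xb."""
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    if Xa.shape[1] != Xb.shape[1]:
        raise KernelParameterError(
            f"feature dimensions differ: {Xa.shape[1]} vs {Xb.shape[1]}"
        )
    if spec.family == "linear":
        return Xa @ Xb.T
    if spec.family == "polynomial":
        return (Xa @ Xb.T + 1.0) ** spec.degree
    if spec.family == "rbf":
        sq = cdist(Xa, Xb, metric="sqeuclidean")
        return np.exp(-sq / (2.0 * spec.sigma**2))
    raise KernelParameterError(
        "weighted kernels are combined from precomputed Grams; use weighted_kernel"
    )


def median_sigma(X_pos: np.ndarray, X_neg: np.ndarray) -> float:
    """Median over positives of the distance to the closest negative."""
    X_pos = np.atleast_2d(X_pos)
    X_neg = np.atleast_2d(X_neg)
    if X_pos.size == 0 or X_neg.size == 0:
        raise ValueError("both classes must be non-empty")
    closest = cdist(X_pos, X_neg).min(axis=1)
    sigma = float(np.median(closest))
    if sigma == 0.0:
        raise ValueError("degenerate sigma: median closest-negative distance is 0")
    return sigma


def sigma_grid(lo: float = 1e-2, hi: float = 1e1, n_points: int = 7) -> np.ndarray:
    """Log-uniform sigma candidates, endpoints included."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points == 1:
        return np.array([lo])
    if lo >= hi:
        raise ValueError("need lo < hi")
    return np.geomspace(lo, hi, n_points)


def weighted_kernel(
    Km: np.ndarray, Kc: np.ndarray, f1_m: float, f1_c: float
) -> np.ndarray:
    """F1-weighted sum of two Gram matrices over the same genes."""
    Km = np.asarray(Km, dtype=float)
    Kc = np.asarray(Kc, dtype=float)
    if Km.shape != Kc.shape:
        raise ValueError(f"shape mismatch: {Km.shape} vs {Kc.shape}")
    if f1_m < 0 or f1_c < 0:
        raise ValueError("weights must be non-negative")
    return f1_m * Km + f1_c * Kc


def check_gram(K: np.ndarray, name: str = "K") -> np.ndarray:
    """Validate symmetry and positive semidefiniteness of a Gram matrix."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{name} is not square: {K.shape}")
    asym = np.max(np.abs(K - K.T))
    if asym > SYMMETRY_TOL * max(1.0, np.max(np.abs(K))):
        raise ValueError(f"{name} is not symmetric (max asymmetry {asym:.3g})")
    eigmin = float(np.linalg.eigvalsh(K).min())
    tol = PSD_TOL_FACTOR * max(np.trace(K), 1.0)
    if eigmin < -tol:
        raise ValueError(
            f"{name} is not PSD: min eigenvalue {eigmin:.6g} < -{tol:.3g}"
        )
    return K


@dataclass(frozen=True)
class KernelMatrix:
    """Gram matrix tied to an ordered gene list."""

    gene_ids: tuple[str, ...]
    K: np.ndarray

    def __post_init__(self) -> None:
        if self.K.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match gene count")
        check_gram(self.K)

    def to_tsv(self, path: str | Path, meta=None) -> Path:
        df = pd.DataFrame(self.K, index=self.gene_ids, columns=self.gene_ids)
        df.insert(0, "gene_id", df.index)
        return io.write_table(df, path, meta=meta)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KernelMatrix":
        df = io.read_table(path).set_index("gene_id")
        return cls(tuple(df.index), df.to_numpy())
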