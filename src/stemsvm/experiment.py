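"""Experiment wiring: the 7 data modes x 3 kernels grid, training-list
validation, and the packaged expert-curated training gene list.

Data modes: micro (expression only), chip_binary / chip_contin (binding
only), simple_binary / simple_contin (concatenated 91 features, one
kernel), weight_binary / weight_contin (one kernel per data type,
combined with F1 weights from each single-type classifier's own LOOCV).
Row labels follow the ``mode_kernel`` scheme, e.g. ``weight_contin_RBF``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stemsvm import io
from stemsvm.classify import KernelModel
from stemsvm.evaluate import ConfusionCounts, LoocvResult, confusion_metrics, loocv
from stemsvm.kernels import KernelSpec, compute_kernel, median_sigma, sigma_grid, weighted_kernel

MODES = (
    "micro",
    "chip_binary",
    "chip_contin",
    "weight_binary",
    "weight_contin",
    "simple_binary",
    "simple_contin",
)
KERNELS = ("linear", "poly", "RBF")

_FAMILY = {"linear": "linear", "poly": "polynomial", "RBF": "rbf"}


class TrainingListError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid settings with YAML round-trip support."""

    modes: tuple[str, ...] = MODES
    kernels: tuple[str, ...] = KERNELS
    C: float = 1.0
    d0: float = 5000.0
    window: int = 1000
    sigma_strategy: str = "median"  # median | grid
    sigma_lo: float = 1e-2
    sigma_hi: float = 1e1
    sigma_points: int = 7
    nested: bool = True
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.modes:
            if m not in MODES:
                raise ValueError(f"unknown data mode {m!r}")
        for k in self.kernels:
            if k not in KERNELS:
                raise ValueError(f"unknown kernel {k!r}")
        if self.sigma_strategy not in ("median", "grid"):
            raise ValueError("sigma_strategy must be 'median' or 'grid'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("modes", "kernels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "modes": list(self.modes),
            "kernels": list(self.kernels),
            "C": self.C,
            "d0": self.d0,
            "window": self.window,
            "sigma_strategy": self.sigma_strategy,
            "sigma_lo": self.sigma_lo,
            "sigma_hi": self.sigma_hi,
            "sigma_points": self.sigma_points,
            "nested": self.nested,
            "seed": self.seed,
        }


def mode_blocks(
    mode: str, Xm: np.ndarray, Xb: np.ndarray, Xc: np.ndarray
) -> list[np.ndarray]:
    """Feature blocks entering the kernel(s) for a data mode.

    One block -> a single kernel on it; two blocks -> the F1-weighted
    two-kernel combination.
    """
    if mode == "micro":
        return [Xm]
    if mode == "chip_binary":
        return [Xb]
    if mode == "chip_contin":
        return [Xc]
    if mode == "simple_binary":
        return [np.hstack([Xm, Xb])]
    if mode == "simple_contin":
        return [np.hstack([Xm, Xc])]
    if mode == "weight_binary":
        return [Xm, Xb]
    if mode == "weight_contin":
        return [Xm, Xc]
    raise ValueError(f"unknown data mode {mode!r}")


def _specs_for_block(
    X: np.ndarray, y: np.ndarray, kernel: str, config: ExperimentConfig
) -> list[KernelSpec]:
    family = _FAMILY[kernel]
    if family == "linear":
        return [KernelSpec("linear")]
    if family == "polynomial":
        return [KernelSpec("polynomial", degree=3)]
    if config.sigma_strategy == "median":
        sig = median_sigma(X[y == 1], X[y == -1])
        return [KernelSpec("rbf", sigma=sig)]
    return [
        KernelSpec("rbf", sigma=float(s))
        for s in sigma_grid(config.sigma_lo, config.sigma_hi, config.sigma_points)
    ]


def _f1_weight(res: LoocvResult) -> float:
    f1 = confusion_metrics(res.confusion).f1
    return 0.0 if f1 is None else f1


def evaluate_mode(
    mode: str,
    kernel: str,
    Xm: np.ndarray,
    Xb: np.ndarray,
    Xc: np.ndarray,
    y: np.ndarray,
    config: ExperimentConfig,
    gene_ids=None,
) -> tuple[LoocvResult, KernelModel]:
    """LOOCV result and a full-data fitted model for one grid cell."""
    blocks = mode_blocks(mode, Xm, Xb, Xc)
    if len(blocks) == 1:
        X = blocks[0]
        specs = _specs_for_block(X, y, kernel, config)
        candidates = [(s.label(), compute_kernel(X, X, s)) for s in specs]
        result = loocv(candidates, y, C=config.C, nested=config.nested, gene_ids=gene_ids)
        chosen_label = result.predictions["chosen"].iloc[-1]
        chosen = next(s for s in specs if s.label() == chosen_label)
        model = KernelModel(
            blocks=[(np.arange(X.shape[1]), chosen, 1.0)], C=config.C
        ).fit(X, y, gene_ids=gene_ids)
        # weighted modes keep per-block column indexing over the hstack
        return result, model

    # weighted combination: one kernel per data type, F1 weights from
    # each single-type classifier's own LOOCV on the training set
    Xa, Xbk = blocks
    spec_a = _specs_for_block(Xa, y, kernel, config)[0]
    spec_b = _specs_for_block(Xbk, y, kernel, config)[0]
    Ka = compute_kernel(Xa, Xa, spec_a)
    Kb = compute_kernel(Xbk, Xbk, spec_b)
    f1_a = _f1_weight(loocv([(spec_a.label(), Ka)], y, C=config.C))
    f1_b = _f1_weight(loocv([(spec_b.label(), Kb)], y, C=config.C))
    K = weighted_kernel(Ka, Kb, f1_a, f1_b)
    label = f"{f1_a:.3f}*{spec_a.label()} + {f1_b:.3f}*{spec_b.label()}"
    result = loocv([(label, K)], y, C=config.C, gene_ids=gene_ids)
    na = Xa.shape[1]
    model = KernelModel(
        blocks=[
            (np.arange(na), spec_a, f1_a),
            (np.arange(na, na + Xbk.shape[1]), spec_b, f1_b),
        ],
        C=config.C,
    ).fit(np.hstack([Xa, Xbk]), y, gene_ids=gene_ids)
    return result, model


def run_experiment_grid(
    Xm: np.ndarray,
    Xb: np.ndarray,
    Xc: np.ndarray,
    y: np.ndarray,
    config: ExperimentConfig | None = None,
    gene_ids=None,
    return_models: bool = False,
):
    """One row of confusion counts and rates per (data mode, kernel).

    Columns mirror the evaluation-table layout: config, TP, FP, TN, FN,
    TPR, FPR, accuracy.
    """
    config = config or ExperimentConfig()
    rows = []
    models: dict[str, KernelModel] = {}
    for mode in config.modes:
        for kernel in config.kernels:
            label = f"{mode}_{kernel}"
            result, model = evaluate_mode(
                mode, kernel, Xm, Xb, Xc, y, config, gene_ids=gene_ids
            )
            c = result.confusion
            m = confusion_metrics(c)
            rows.append(
                {
                    "config": label,
                    "TP": c.tp,
                    "FP": c.fp,
                    "TN": c.tn,
                    "FN": c.fn,
                    "TPR": m.tpr,
                    "FPR": m.fpr,
                    "accuracy": m.accuracy,
                }
            )
            models[label] = model
    table = pd.DataFrame(rows)
    if return_models:
        return table, models
    return table


def validate_training_list(
    path: str | Path | None = None,
    positives_path: str | Path | None = None,
    negatives_path: str | Path | None = None,
) -> tuple[list[str], list[str]]:
    """Parse a labeled training gene list.

    Either a two-column TSV (gene_id, label with positives marked
    'MSMG' or 'positive') or two one-gene-per-line files. Duplicate or
    cross-listed genes are rejected.
    """
    if path is not None:
        df = io.read_table(path)
        if df.empty:
            raise TrainingListError("training list is empty")
        if list(df.columns[:2]) != ["gene_id", "label"]:
            raise TrainingListError("expected columns: gene_id, label")
        pos = [r.gene_id for r in df.itertuples() if r.label in ("MSMG", "positive")]
        neg = [r.gene_id for r in df.itertuples() if r.label not in ("MSMG", "positive")]
    else:
        if positives_path is None or negatives_path is None:
            raise TrainingListError("provide one TSV or two gene-list files")
        pos = io.read_gene_list(positives_path)
        neg = io.read_gene_list(negatives_path)
    if not pos or not neg:
        raise TrainingListError("both classes must be non-empty")
    for name, lst in (("positive", pos), ("negative", neg)):
        dupes = {g for g in lst if lst.count(g) > 1}
        if dupes:
            raise TrainingListError(f"duplicated {name} gene(s): {sorted(dupes)}")
    crossed = set(pos) & set(neg)
    if crossed:
        raise TrainingListError(f"gene(s) listed in both classes: {sorted(crossed)}")
    return pos, neg


def training_gene_fixture_path() -> Path:
    """Path to the packaged expert-curated training gene list."""
    return Path(resources.files("stemsvm").joinpath("data/training_genes.tsv"))


def load_training_genes() -> tuple[list[str], list[str]]:
    """Packaged training list: (positive gene symbols, negative gene symbols)."""
    return validate_training_list(training_gene_fixture_path())
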