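"""Per-gene feature construction: scaled expression plus TF-binding scores.

Expression vectors are log2-transformed and scaled to unit Euclidean
norm. Binding is summarized per (gene, TF) either as a binary
presence/absence call in a TSS window, or as a continuous distance-decay
weighted sum of peak intensities, ``a = sum_k g_k * exp(-d_k / d0)``,
which is then log-transformed and quantile-normalized across TF columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from stemsvm import io
from stemsvm.synthetic import GeneAnnotation

DEFAULT_D0 = 5000.0
DEFAULT_WINDOW = 1000

#: assemble_features modes -> expected column count
MODES = {
    "micro": 79,
    "chip_binary": 12,
    "chip_contin": 12,
    "combined_binary": 91,
    "combined_contin": 91,
}


class DegenerateVectorError(ValueError):
    """All log2 expression values are zero; the scaled vector is undefined."""


@dataclass(frozen=True)
class FeatureMatrix:
    """Genes x features values with per-column provenance.

    provenance columns: feature, dataset, mode
    (mode in {expression, chip-binary, chip-continuous}).
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.provenance["feature"]):
            raise ValueError("provenance rows must match value columns in order")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_files(self, prefix: str | Path, meta=None) -> tuple[Path, Path]:
        prefix = Path(prefix)
        vals = self.values.copy()
        vals.insert(0, "gene_id", vals.index)
        p1 = io.write_table(vals, prefix.with_suffix(".tsv"), meta=meta)
        p2 = io.write_table(
            self.provenance, Path(str(prefix) + ".provenance.tsv"), meta=meta
        )
        return p1, p2

    @classmethod
    def from_files(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        vals = io.read_table(prefix.with_suffix(".tsv")).set_index("gene_id")
        vals.index.name = None
        prov = io.read_table(Path(str(prefix) + ".provenance.tsv"))
        return cls(vals, prov)


def normalize_expression(
    E: np.ndarray, pseudocount: float | None = None
) -> np.ndarray:
    """Scale one gene's expression vector: X_i = log2(E_i) / ||log2(E)||_2.

    Parameters
    ----------
    E : positive expression values (any length).
    pseudocount : if given, added to E before the log; otherwise
        non-positive entries raise ValueError.
    """
    E = np.asarray(E, dtype=float)
    if pseudocount is not None:
        E = E + pseudocount
    if np.any(E <= 0):
        raise ValueError("expression values must be strictly positive")
    logs = np.log2(E)
    norm = np.sqrt(np.sum(logs**2))
    if norm == 0.0:
        raise DegenerateVectorError("all log2(E) values are zero")
    return logs / norm


def normalize_expression_matrix(
    expr: pd.DataFrame, pseudocount: float | None = None
) -> pd.DataFrame:
    """Row-wise unit-norm scaling of an expression matrix."""
    out = np.vstack(
        [normalize_expression(row, pseudocount=pseudocount) for row in expr.to_numpy()]
    )
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _peak_centers(peaks: pd.DataFrame) -> np.ndarray:
    return (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0


def binary_binding(
    peaks: pd.DataFrame, gene: GeneAnnotation, window: int = DEFAULT_WINDOW
) -> int:
    """1 iff any peak center lies within +/- window of the TSS (inclusive)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(peaks) == 0:
        return 0
    sel = peaks["chrom"] == gene.chrom
    if not sel.any():
        return 0
    d = np.abs(_peak_centers(peaks[sel]) - gene.tss)
    return int(np.any(d <= window))


def continuous_binding(
    peaks: pd.DataFrame, gene: GeneAnnotation, d0: float = DEFAULT_D0
) -> float:
    """Distance-decay binding score: sum_k g_k * exp(-d_k / d0).

    d_k is the absolute distance from the TSS to peak k's center
    (strand-ignored); additive over peaks, strictly decreasing in each d_k.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    if len(peaks) == 0:
        return 0.0
    if (peaks["intensity"] < 0).any():
        raise ValueError("peak intensities must be non-negative")
    sel = peaks["chrom"] == gene.chrom
    if not sel.any():
        return 0.0
    sub = peaks[sel]
    d = np.abs(_peak_centers(sub) - gene.tss)
    return float(np.sum(sub["intensity"].to_numpy() * np.exp(-d / d0)))


def quantile_normalize(M: np.ndarray) -> np.ndarray:
    """Force all columns to the mean-quantile reference distribution.

    Stable argsort per column; ties are resolved by original row order,
    so every column's value multiset equals the reference exactly.
    """
    M = np.asarray(M, dtype=float)
    order = np.argsort(M, axis=0, kind="stable")
    ref = np.take_along_axis(M, order, axis=0).mean(axis=1)
    out = np.empty_like(M)
    np.put_along_axis(out, order, ref[:, None], axis=0)
    return out


def transform_binding_matrix(A: pd.DataFrame) -> pd.DataFrame:
    """log2(a + 1) then quantile normalization across TF columns."""
    if (A.to_numpy() < 0).any():
        raise ValueError("binding values must be non-negative")
    if len(A) < 2:
        raise ValueError("need at least 2 genes to quantile-normalize")
    logged = np.log2(A.to_numpy() + 1.0)
    return pd.DataFrame(quantile_normalize(logged), index=A.index, columns=A.columns)


def build_chip_matrices(
    genes: list[GeneAnnotation],
    peak_sets: list[pd.DataFrame],
    window: int = DEFAULT_WINDOW,
    d0: float = DEFAULT_D0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary and transformed-continuous binding matrices (genes x TFs)."""
    tf_names = [
        str(pk["tf"].iloc[0]) if len(pk) else f"tf{j + 1:02d}"
        for j, pk in enumerate(peak_sets)
    ]
    gene_ids = [g.gene_id for g in genes]
    binary = np.zeros((len(genes), len(peak_sets)), dtype=float)
    raw = np.zeros_like(binary)
    for j, pk in enumerate(peak_sets):
        for i, g in enumerate(genes):
            binary[i, j] = binary_binding(pk, g, window=window)
            raw[i, j] = continuous_binding(pk, g, d0=d0)
    binary_df = pd.DataFrame(binary, index=gene_ids, columns=tf_names)
    contin_df = transform_binding_matrix(
        pd.DataFrame(raw, index=gene_ids, columns=tf_names)
    )
    return binary_df, contin_df


def _provenance(columns, dataset_of, mode) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature": list(columns), "dataset": dataset_of, "mode": mode}
    )


def assemble_features(
    expression: pd.DataFrame | None,
    chip_binary: pd.DataFrame | None,
    chip_contin: pd.DataFrame | None,
    mode: str,
    layout=None,
) -> FeatureMatrix:
    """Concatenate the requested blocks into a FeatureMatrix.

    mode: micro (79) | chip_binary (12) | chip_contin (12) |
    combined_binary (91) | combined_contin (91).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(MODES)}")

    def dataset_tags(cols):
        if layout is None:
            return ["expression"] * len(cols)
        by_name = {d.name: d.dataset for d in layout}
        return [by_name.get(c, "expression") for c in cols]

    blocks: list[tuple[pd.DataFrame, pd.DataFrame]] = []
    if mode in ("micro", "combined_binary", "combined_contin"):
        if expression is None:
            raise ValueError("expression block required for this mode")
        blocks.append(
            (expression, _provenance(expression.columns, dataset_tags(expression.columns), "expression"))
        )
    if mode in ("chip_binary", "combined_binary"):
        if chip_binary is None:
            raise ValueError("chip_binary block required for this mode")
        blocks.append(
            (chip_binary, _provenance(chip_binary.columns, "chip", "chip-binary"))
        )
    if mode in ("chip_contin", "combined_contin"):
        if chip_contin is None:
            raise ValueError("chip_contin block required for this mode")
        blocks.append(
            (chip_contin, _provenance(chip_contin.columns, "chip", "chip-continuous"))
        )

    index = blocks[0][0].index
    for blk, _ in blocks[1:]:
        if list(blk.index) != list(index):
            raise ValueError("gene sets/order differ between feature blocks")
    values = pd.concat([blk for blk, _ in blocks], axis=1)
    prov = pd.concat([p for _, p in blocks], ignore_index=True)
    fm = FeatureMatrix(values, prov)
    if len(fm.feature_names) != MODES[mode]:
        raise ValueError(
            f"mode {mode} expected {MODES[mode]} columns, got {len(fm.feature_names)}"
        )
    return fm
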