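"""Synthetic data generator emulating the study's data structure.

Produces a labeled gene universe on a single artificial chromosome, an
expression matrix over the 79-condition layout, 12 transcription-factor
peak sets with class-dependent binding near TSSs, and candidate gene
lists with planted enrichment. Everything is deterministic per seed:
each operation draws from its own seeded stream so outputs are stable
regardless of call order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from stemsvm import io
from stemsvm.layout import StudyLayout, LayoutError, default_layout

N_TFS = 12
_PEAK_HALFWIDTH = 100

# independent substream ids, mixed with the seed
_STREAM_UNIVERSE, _STREAM_EXPR, _STREAM_PEAKS, _STREAM_LISTS = range(4)


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene anchored by its TSS, with a training label.

    ``signal`` is the latent ground-truth class used by the simulator;
    it equals the label for labeled genes and is hidden class membership
    for unlabeled ones (candidate-list plumbing).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    label: str  # positive | negative | unlabeled
    signal: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ConfigurationError(f"negative TSS for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ConfigurationError(f"bad strand {self.strand!r}")
        if self.label not in {"positive", "negative", "unlabeled"}:
            raise ConfigurationError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; see field names for units."""

    n_pos: int = 46
    n_neg: int = 70
    n_unlabeled: int = 0
    effect_size: float = 2.0  # multiplier on class-dependent log2 shifts
    noise_sd: float = 0.5  # log2-scale s.d. of multiplicative noise
    p_peak_pos: float = 0.8
    p_peak_neg: float = 0.2
    peak_distance_scale: float = 2000.0  # bp, Laplace scale of TSS offsets
    intensity_log_mean: float = 1.0
    intensity_log_sd: float = 0.5
    chrom_length: int = 50_000_000
    base_log2: float = 7.0
    enrichment: float = 0.8  # signal fraction of the positive candidate list
    candidate_list_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ConfigurationError("need at least 2 genes per labeled class")
        if self.n_unlabeled < 0:
            raise ConfigurationError("n_unlabeled must be >= 0")
        for name in ("p_peak_pos", "p_peak_neg", "enrichment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.peak_distance_scale <= 0:
            raise ConfigurationError("peak_distance_scale must be > 0")
        n_total = self.n_pos + self.n_neg + self.n_unlabeled
        if self.chrom_length < 10 * n_total:
            raise ConfigurationError("chrom_length too small for gene count")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_universe(config: SimulationConfig) -> list[GeneAnnotation]:
    """Draw the gene universe: labels, collision-free TSSs, strands.

    The first ``ceil(candidate_list_size * enrichment)`` unlabeled genes
    carry latent signal so candidate lists can be planted with enrichment.
    """
    rng = _rng(config, _STREAM_UNIVERSE)
    n = config.n_pos + config.n_neg + config.n_unlabeled
    positions: list[int] = []
    seen: set[int] = set()
    while len(positions) < n:
        for p in rng.integers(0, config.chrom_length, size=n):
            if p not in seen:
                seen.add(int(p))
                positions.append(int(p))
                if len(positions) == n:
                    break
    strands = rng.choice(["+", "-"], size=n)
    labels = (
        ["positive"] * config.n_pos
        + ["negative"] * config.n_neg
        + ["unlabeled"] * config.n_unlabeled
    )
    n_sig_unlab = min(
        config.n_unlabeled,
        int(np.ceil(config.candidate_list_size * config.enrichment)),
    )
    genes = []
    width = len(str(n))
    unlab_seen = 0
    for i, (pos, strand, label) in enumerate(zip(positions, strands, labels)):
        if label == "positive":
            signal = True
        elif label == "negative":
            signal = False
        else:
            signal = unlab_seen < n_sig_unlab
            unlab_seen += 1
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i:0{width}d}",
                chrom="chrS",
                tss=pos,
                strand=str(strand),
                label=label,
                signal=signal,
            )
        )
    return genes


def _class_template(layout: StudyLayout) -> np.ndarray:
    """Per-feature shift (in [-1, 1]) applied to signal-carrying genes.

    Elevated in ES, depressed in EB; decaying linearly along every
    differentiation/RA/knockdown time course.
    """
    tmpl = np.empty(len(layout))
    for j, desc in enumerate(layout):
        if desc.dataset == "esc_vs_eb":
            tmpl[j] = 1.0 if desc.condition == "ES" else -1.0
        else:
            n_points = sum(1 for d in layout if d.dataset == desc.dataset)
            tmpl[j] = 1.0 - 2.0 * desc.time / (n_points - 1)
    return tmpl


def simulate_expression(
    genes: list[GeneAnnotation],
    layout: StudyLayout | None,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Strictly positive expression matrix (genes x 79 layout features)."""
    layout = layout if layout is not None else default_layout()
    if len(layout) != 79:
        raise LayoutError(f"expected 79 layout descriptors, got {len(layout)}")
    rng = _rng(config, _STREAM_EXPR)
    tmpl = _class_template(layout)
    sign = np.array([1.0 if g.signal else 0.0 for g in genes])
    log2x = (
        config.base_log2
        + config.effect_size * np.outer(sign, tmpl)
        + rng.normal(0.0, config.noise_sd, size=(len(genes), len(layout)))
    )
    values = np.exp2(log2x)
    return pd.DataFrame(values, index=[g.gene_id for g in genes], columns=layout.names)


def simulate_chip_peaks(
    genes: list[GeneAnnotation],
    config: SimulationConfig,
    n_tfs: int = N_TFS,
) -> list[pd.DataFrame]:
    """One peak table per TF: columns chrom, start, end, tf, intensity.

    Signal genes are bound with probability ``p_peak_pos``; background
    genes with ``p_peak_neg``. Peak centers are Laplace-offset from the
    TSS, intensities log-normal.
    """
    if not genes:
        raise ConfigurationError("gene list is empty")
    if config.p_peak_pos < config.p_peak_neg:
        warnings.warn(
            "p_peak_pos < p_peak_neg: binding signal is inverted",
            stacklevel=2,
        )
    peak_sets = []
    lo, hi = _PEAK_HALFWIDTH, config.chrom_length - _PEAK_HALFWIDTH - 1
    for j in range(n_tfs):
        rng = np.random.default_rng([config.seed, _STREAM_PEAKS, j])
        rows = []
        tf_name = f"tf{j + 1:02d}"
        for g in genes:
            p = config.p_peak_pos if g.signal else config.p_peak_neg
            if rng.random() >= p:
                continue
            n_peaks = 1 + rng.poisson(0.3)
            offsets = rng.laplace(0.0, config.peak_distance_scale, size=n_peaks)
            intens = rng.lognormal(
                config.intensity_log_mean, config.intensity_log_sd, size=n_peaks
            )
            for off, g_k in zip(offsets, intens):
                center = int(np.clip(round(g.tss + off), lo, hi))
                rows.append(
                    (
                        g.chrom,
                        center - _PEAK_HALFWIDTH,
                        center + _PEAK_HALFWIDTH,
                        tf_name,
                        float(g_k),
                    )
                )
        peak_sets.append(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "tf", "intensity"])
        )
    return peak_sets


def make_candidate_lists(
    genes: list[GeneAnnotation], config: SimulationConfig
) -> tuple[list[str], list[str]]:
    """Planted-enrichment candidate lists drawn from the unlabeled pool.

    The positive list mixes latent-signal genes (fraction ``enrichment``)
    with background genes; the negative list is background only and
    disjoint from the positive list.
    """
    size = config.candidate_list_size
    unlabeled = [g for g in genes if g.label == "unlabeled"]
    signal_pool = [g.gene_id for g in unlabeled if g.signal]
    background = [g.gene_id for g in unlabeled if not g.signal]
    n_sig = min(len(signal_pool), int(np.ceil(size * config.enrichment)))
    n_bg_pos = size - n_sig
    if n_bg_pos + size > len(background):
        raise ConfigurationError(
            "not enough unlabeled background genes for two disjoint "
            f"candidate lists of size {size}"
        )
    rng = _rng(config, _STREAM_LISTS)
    bg = list(rng.permutation(background))
    pos_list = sorted(signal_pool[:n_sig] + bg[:n_bg_pos])
    neg_list = sorted(bg[n_bg_pos : n_bg_pos + size])
    return pos_list, neg_list


def write_fixtures(
    genes: list[GeneAnnotation],
    expression: pd.DataFrame,
    peaks: list[pd.DataFrame],
    out_dir: str | Path,
    candidates: tuple[list[str], list[str]] | None = None,
    meta: dict | None = None,
) -> dict[str, Path]:
    """Serialize a simulated dataset as plain-text BED/TSV/list files."""
    gene_ids = {g.gene_id for g in genes}
    if set(expression.index) != gene_ids:
        raise ValueError("expression matrix gene set differs from annotation")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bed_rows = [(g.chrom, g.tss, g.tss + 1, g.gene_id, 0, g.strand) for g in genes]
    paths["genes"] = io.write_bed(bed_rows, out_dir / "genes.bed", meta=meta)

    expr = expression.copy()
    expr.insert(0, "gene_id", expr.index)
    paths["expression"] = io.write_table(expr, out_dir / "expression.tsv", meta=meta)

    for j, pk in enumerate(peaks):
        name = f"peaks_tf{j + 1:02d}"
        paths[name] = io.write_bed(
            list(pk.itertuples(index=False, name=None)),
            out_dir / f"{name}.bed",
            meta=meta,
        )

    for label in ("positive", "negative", "unlabeled"):
        ids = [g.gene_id for g in genes if g.label == label]
        paths[label] = io.write_gene_list(ids, out_dir / f"{label}.txt", meta=meta)

    if candidates is not None:
        pos_list, neg_list = candidates
        paths["candidates_pos"] = io.write_gene_list(
            pos_list, out_dir / "candidates_pos.txt", meta=meta
        )
        paths["candidates_neg"] = io.write_gene_list(
            neg_list, out_dir / "candidates_neg.txt", meta=meta
        )
    return paths


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    df = io.read_bed(path, ["chrom", "start", "end", "gene_id", "score", "strand"])
    return [
        GeneAnnotation(
            gene_id=r.gene_id,
            chrom=r.chrom,
            tss=int(r.start),
            strand=r.strand,
            label="unlabeled",
        )
        for r in df.itertuples()
    ]


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    return io.read_bed(path, ["chrom", "start", "end", "tf", "intensity"])


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = io.read_table(path).set_index("gene_id")
    df.index.name = None
    return df
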