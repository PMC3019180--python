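"""Plain-text I/O helpers: TSV tables, BED intervals, gene lists.

All writers accept an optional ``meta`` mapping that is emitted as
``# key: value`` comment lines at the top of the file; all readers skip
``#`` comment lines. Floats are written with ``repr`` precision so a
round trip through disk is exact.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml


def meta_header(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def config_hash(obj: object) -> str:
    """Short stable hash of any YAML-serializable configuration object."""
    dumped = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(dumped.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
    index: bool = False,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(meta_header(meta))
        # %.17g guarantees an exact float round trip through the file
        df.to_csv(fh, sep="\t", index=index, float_format="%.17g")
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col, float_precision="round_trip"
    )


def write_gene_list(
    gene_ids: Iterable[str],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(meta_header(meta))
        for gid in gene_ids:
            fh.write(f"{gid}\n")
    return path


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_bed(
    rows: Iterable[tuple],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> Path:
    """Write BED-like rows (tuples of columns) as a tab-separated file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(meta_header(meta))
        for row in rows:
            fh.write("\t".join(repr(c) if isinstance(c, float) else str(c) for c in row))
            fh.write("\n")
    return path


def read_bed(path: str | Path, columns: list[str]) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=columns,
        float_precision="round_trip",
    )
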