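"""Readers and writers for the community CSV / metadata CSV / TSV outputs.

Community CSV: first column the plot id, remaining columns species covers
(percent). Metadata CSV: plot_id, management (mown/abandoned), expansive
cover, and optional environmental columns. Output TSVs carry a header
comment with a hash of the run configuration so results are traceable to
their options.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import AbundanceTable

__all__ = [
    "PlotMetadata",
    "read_community",
    "write_community",
    "read_metadata",
    "write_metadata",
    "check_plot_ids",
    "config_hash",
    "write_tsv",
]

MANAGEMENT_LEVELS = ("mown", "abandoned")


@dataclass
class PlotMetadata:
    """Per-plot covariates: management, expansive cover, environment."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        required = {"plot_id", "management", "expansive_cover"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing required columns: {sorted(missing)}")
        df = df.copy()
        df["plot_id"] = df["plot_id"].astype(str)
        if df["plot_id"].duplicated().any():
            dupes = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
            raise ValueError(f"duplicate plot ids in metadata: {dupes}")
        bad = ~df["management"].isin(MANAGEMENT_LEVELS)
        if bad.any():
            rows = df.loc[bad, ["plot_id", "management"]].to_dict("records")
            raise ValueError(
                f"management outside {MANAGEMENT_LEVELS}: {rows}"
            )
        cover = pd.to_numeric(df["expansive_cover"], errors="raise")
        if ((cover < 0) | (cover > 100)).any():
            raise ValueError("expansive_cover must lie in [0, 100]")
        df["expansive_cover"] = cover
        self.table = df

    @property
    def plot_ids(self) -> list[str]:
        return list(self.table["plot_id"])

    def aligned_to(self, plot_ids: list[str]) -> pd.DataFrame:
        df = self.table.set_index("plot_id")
        return df.loc[[str(p) for p in plot_ids]].reset_index()


def read_community(path: str | Path) -> AbundanceTable:
    """Read a plots-by-species cover CSV (first column: plot id)."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError("community CSV needs a plot-id column and >= 1 species")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cover cell in {path}: {exc}") from exc
    return AbundanceTable(list(df.index), [str(c) for c in df.columns], values)


def write_community(table: AbundanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index_label="plot_id")


def read_metadata(path: str | Path) -> PlotMetadata:
    return PlotMetadata(pd.read_csv(path, comment="#"))


def write_metadata(meta: PlotMetadata | pd.DataFrame, path: str | Path) -> None:
    df = meta.table if isinstance(meta, PlotMetadata) else meta
    df.to_csv(path, index=False)


def check_plot_ids(table: AbundanceTable, meta: PlotMetadata) -> None:
    """Cross-check id sets; errors list every mismatching plot."""
    community = set(table.plot_ids)
    metadata = set(meta.plot_ids)
    only_community = sorted(community - metadata)
    only_metadata = sorted(metadata - community)
    if only_community or only_metadata:
        parts = []
        if only_community:
            parts.append(f"plots missing from metadata: {only_community}")
        if only_metadata:
            parts.append(f"plots missing from community table: {only_metadata}")
        raise ValueError("; ".join(parts))


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv(
    df: pd.DataFrame, path: str | Path, config: dict | None = None, index: bool = False
) -> None:
    """Write a TSV, prefixed by a config-hash header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=index)
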