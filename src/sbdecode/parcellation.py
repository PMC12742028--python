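"""Atlas-based aggregation of voxel values and feature-table I/O.

The packaged atlas reproduces the cardinality and naming scheme of a merged
AAL parcellation: small neighbouring regions are merged and all Cerebellum
and Vermis labels are excluded, leaving 62 cortical/subcortical regions.
The merge table ships as editable TSV data (``data/aal62_merge.tsv``), so a
different merge scheme can be substituted without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import STATES

EXCLUDE = "EXCLUDE"
METADATA_COLUMNS = ["participant", "state", "epoch_idx"]


@dataclass(frozen=True)
class AtlasMap:
    """Raw-label → merged-label table; ``EXCLUDE`` drops a raw region."""

    merge_table: dict[str, str]

    def __post_init__(self) -> None:
        if not self.merge_table:
            raise ValueError("merge table is empty")

    @property
    def merged_labels(self) -> list[str]:
        """Merged region names in first-appearance order (the feature namespace)."""
        seen: dict[str, None] = {}
        for merged in self.merge_table.values():
            if merged != EXCLUDE and merged not in seen:
                seen[merged] = None
        return list(seen)

    def merged_of(self, raw_label: str) -> str:
        try:
            return self.merge_table[raw_label]
        except KeyError:
            raise KeyError(f"raw region label {raw_label!r} not in atlas") from None


def load_atlas(path: str | Path) -> AtlasMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["raw_label", "merged_label"]:
        raise ValueError(
            "atlas merge table must have columns raw_label, merged_label"
        )
    if df["raw_label"].duplicated().any():
        dupes = df.loc[df["raw_label"].duplicated(), "raw_label"].tolist()
        raise ValueError(f"duplicate raw labels in atlas: {dupes}")
    return AtlasMap(dict(zip(df["raw_label"], df["merged_label"])))


def default_atlas() -> AtlasMap:
    """The packaged 62-region merged-AAL table."""
    with resources.as_file(
        resources.files("sbdecode.data").joinpath("aal62_merge.tsv")
    ) as p:
        return load_atlas(p)


def parcellate(
    voxel_values: dict[str, float],
    voxel_labels: dict[str, str],
    atlas: AtlasMap,
) -> dict[str, float]:
    """Unweighted mean of voxel values within each merged region.

    Parameters
    ----------
    voxel_values
        Voxel id → value.
    voxel_labels
        Voxel id → raw atlas label.
    atlas
        Merge table; raw labels mapped to ``EXCLUDE`` contribute nothing.

    Raises
    ------
    KeyError
        If any voxel has no label or an unknown raw label; the message lists
        the offending voxel ids.
    """
    missing = [v for v in voxel_values if v not in voxel_labels]
    if missing:
        raise KeyError(f"voxels without atlas assignment: {missing}")
    unknown = [
        v for v in voxel_values if voxel_labels[v] not in atlas.merge_table
    ]
    if unknown:
        raise KeyError(f"voxels with unknown raw labels: {unknown}")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    # accumulate in sorted voxel order so the result is exactly invariant
    # to the caller's enumeration order (floating addition is not associative)
    for vox in sorted(voxel_values):
        val = voxel_values[vox]
        merged = atlas.merged_of(voxel_labels[vox])
        if merged == EXCLUDE:
            continue
        sums[merged] = sums.get(merged, 0.0) + float(val)
        counts[merged] = counts.get(merged, 0) + 1
    return {region: sums[region] / counts[region] for region in sums}


# -- feature-table I/O ---------------------------------------------------


def validate_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing metadata columns: {missing}")
    bad_states = sorted(set(table["state"]) - set(STATES))
    if bad_states:
        raise ValueError(f"unknown state labels in feature table: {bad_states}")
    dupes = table.duplicated(subset=["participant", "epoch_idx"])
    if dupes.any():
        keys = (
            table.loc[dupes, ["participant", "epoch_idx"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"duplicate (participant, epoch_idx) keys: {keys[:5]}")


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"participant": str})
    validate_feature_table(table)
    # feature columns are real-valued even when their text happens to parse
    # as integers
    for col in feature_columns(table):
        table[col] = table[col].astype(float)
    return table


def feature_columns(table: pd.DataFrame, prefix: str | None = None) -> list[str]:
    """Non-metadata columns, optionally filtered by ``prefix__`` namespace."""
    cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    if prefix is not None:
        cols = [c for c in cols if c.startswith(prefix + "__")]
    return cols
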