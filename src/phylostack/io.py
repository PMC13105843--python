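"""Readers and writers for the tool's text formats.

Delimited text (TSV by default, comma for ``.csv`` or on request) for
abundance matrices, taxonomy rank tables and sample metadata; Newick for
trees; JSON for serialized view states and layout specs; YAML for style
configuration.
"""

from __future__ import annotations

import json
import os

import pandas as pd
import yaml

from .tables import AbundanceTable, TaxonomyTable
from .tree import Hierarchy, parse_newick, write_newick
from .view import ViewState, state_from_dict, state_to_dict

__all__ = [
    "guess_sep",
    "read_abundance",
    "write_abundance",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_newick_file",
    "write_newick_file",
    "read_state",
    "write_state",
    "write_layout_json",
    "load_config",
]


def guess_sep(path, sep: str | None = None) -> str:
    if sep:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_abundance(path, sep: str | None = None) -> AbundanceTable:
    """Samples × taxa matrix: first column sample ids, header row taxon ids."""
    df = pd.read_csv(path, sep=guess_sep(path, sep), index_col=0)
    return AbundanceTable(df)


def write_abundance(a: AbundanceTable, path, sep: str | None = None) -> None:
    a.data.to_csv(path, sep=guess_sep(path, sep))


def read_taxonomy(path, sep: str | None = None, id_first: bool = False) -> TaxonomyTable:
    """Rank table: header row = rank names (coarse → fine).

    With ``id_first`` the first column holds the taxon (leaf) identifier and
    the remaining columns the ranks; the identifier is appended as the finest
    level so it becomes the leaf label.
    """
    df = pd.read_csv(path, sep=guess_sep(path, sep), dtype=str)
    if id_first:
        id_col = df.columns[0]
        df = df[[*df.columns[1:], id_col]]
    return TaxonomyTable.from_dataframe(df)


def write_taxonomy(t: TaxonomyTable, path, sep: str | None = None) -> None:
    t.to_dataframe().to_csv(path, sep=guess_sep(path, sep), index=False)


def read_metadata(path, sep: str | None = None) -> dict[str, str]:
    """Two-column table (sample id, group label) → ordered mapping."""
    df = pd.read_csv(path, sep=guess_sep(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"metadata file {path} needs at least two columns (sample, group)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_metadata(groups: dict[str, str], path, sep: str | None = None) -> None:
    pd.DataFrame(
        {"sample": list(groups.keys()), "group": list(groups.values())}
    ).to_csv(path, sep=guess_sep(path, sep), index=False)


def read_newick_file(path) -> Hierarchy:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick_file(h: Hierarchy, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(h) + "\n")


def read_state(path) -> ViewState:
    with open(path, encoding="utf-8") as fh:
        return state_from_dict(json.load(fh))


def write_state(s: ViewState, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(state_to_dict(s), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_layout_json(layout_dict: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(layout_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    """YAML config: ``style`` section for StyleConfig fields plus flag defaults."""
    if path is None or not os.path.exists(path):
        return {}
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must hold a YAML mapping")
    return cfg
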