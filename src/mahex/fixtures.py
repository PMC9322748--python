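"""Packaged reference tables.

The package ships, as plain TSV resources, the printed log2 M values
of the published same-direction and opposite-direction gene sets for
the LPS-treated IBD enteroid/colonoid comparison (25 same-trend genes
over contrasts 3 and 2; 3 genes concordant across contrasts 3, 2 and
1; 20 opposite-trend genes; 3 genes mixed across the three contrasts)
and a GO category membership table for an 11-gene example set.  These
serve as ground truth for the concordance classifier and the category
percentage convention.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "table11_same_direction",
    "table12_same_direction_triple",
    "table13_opposite_direction",
    "table14_mixed_direction_triple",
    "go_membership",
    "fixture_tables",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("mahex").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def table11_same_direction() -> pd.DataFrame:
    """25 genes changing in the same direction in LPS-treated IBD
    colonoids (contrast 3) and enteroids (contrast 2)."""
    return _load("table11_same_direction.tsv")


def table12_same_direction_triple() -> pd.DataFrame:
    """3 genes changing in the same direction across contrasts 3, 2
    and 1 (IBD colonoids, IBD enteroids, tumor-adjacent enteroids)."""
    return _load("table12_same_direction_triple.tsv")


def table13_opposite_direction() -> pd.DataFrame:
    """20 genes changing in opposite directions between LPS-treated
    IBD colonoids (contrast 3) and enteroids (contrast 2)."""
    return _load("table13_opposite_direction.tsv")


def table14_mixed_direction_triple() -> pd.DataFrame:
    """3 genes with mixed directions across contrasts 1, 3 and 2."""
    return _load("table14_mixed_direction_triple.tsv")


def go_membership(subtree: str | None = None) -> pd.DataFrame:
    """GO category membership (``subtree, category, gene``) for the
    11-gene top-DEG example set; optionally filtered to one sub-tree
    (``biological_process``, ``molecular_function`` or
    ``cellular_component``)."""
    df = _load("table4_go_membership.tsv")
    if subtree is not None:
        if subtree not in set(df["subtree"]):
            raise ValueError(f"unknown GO sub-tree {subtree!r}")
        df = df[df["subtree"] == subtree].reset_index(drop=True)
    return df


def fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The three concordance input tables (same-direction pair,
    same-direction triple, opposite-direction pair)."""
    return (
        table11_same_direction(),
        table12_same_direction_triple(),
        table13_opposite_direction(),
    )
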