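"""Sign-concordance classification of genes across contrasts.

Given per-gene log2 ratios (M) from two or three contrasts, genes are
classed by strict sign agreement: ``concordant-up`` when every M is
positive, ``concordant-down`` when every M is negative, ``discordant``
when strict signs disagree, and ``unclassified`` when any M is exactly
zero.  No magnitude threshold is applied — the classification reports
directions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "classify_pair",
    "classify_triple",
    "concordance_counts",
    "collapse_to_gene",
    "ConcordanceResult",
]

CLASSES = ("concordant-up", "concordant-down", "discordant", "unclassified")


def _classify(ms: tuple[float, ...]) -> str:
    for m in ms:
        if not math.isfinite(m):
            raise ValueError("M values must be finite")
    if any(m == 0 for m in ms):
        return "unclassified"
    if all(m > 0 for m in ms):
        return "concordant-up"
    if all(m < 0 for m in ms):
        return "concordant-down"
    return "discordant"


def classify_pair(m1: float, m2: float) -> str:
    """Sign-concordance class of a gene across two contrasts."""
    return _classify((m1, m2))


def classify_triple(m1: float, m2: float, m3: float) -> str:
    """Sign-concordance class of a gene across three contrasts."""
    return _classify((m1, m2, m3))


@dataclass
class ConcordanceResult:
    table: pd.DataFrame          # input columns plus "concordance_class"
    counts: dict[str, int]       # per-class counts (all classes present)

    @property
    def total(self) -> int:
        return len(self.table)

    def members(self, cls: str) -> pd.DataFrame:
        return self.table[self.table["concordance_class"] == cls]


def _m_columns(table: pd.DataFrame, m_columns=None) -> list[str]:
    if m_columns is None:
        m_columns = [c for c in table.columns if c.startswith("M_") or c == "M"]
    if len(m_columns) not in (2, 3):
        raise ValueError("concordance requires two or three M columns")
    return list(m_columns)


def concordance_counts(table: pd.DataFrame, m_columns=None) -> ConcordanceResult:
    """Classify every row of a concordance input table.

    ``m_columns`` names the per-contrast M columns (default: all
    columns starting with ``M_``); rows keep their input order.
    """
    if len(table) == 0:
        raise ValueError("concordance input is empty")
    m_columns = _m_columns(table, m_columns)
    M = table[m_columns].to_numpy(float)
    if not np.isfinite(M).all():
        raise ValueError("M values must be finite")
    out = table.copy()
    cls = np.full(len(table), "discordant", dtype=object)
    cls[(M > 0).all(axis=1)] = "concordant-up"
    cls[(M < 0).all(axis=1)] = "concordant-down"
    cls[(M == 0).any(axis=1)] = "unclassified"
    out["concordance_class"] = cls
    counts = {c: int((cls == c).sum()) for c in CLASSES}
    return ConcordanceResult(table=out, counts=counts)


def collapse_to_gene(table: pd.DataFrame, m_columns=None) -> pd.DataFrame:
    """Collapse a probe-set-level table to one row per gene symbol.

    The representative probe set is the one with the largest |M| in
    the first contrast column (ties: first occurrence in input order).
    """
    if len(table) == 0:
        raise ValueError("concordance input is empty")
    m_columns = _m_columns(table, m_columns)
    first = table[m_columns[0]].abs().to_numpy()
    order = np.arange(len(table))
    df = table.assign(_absM=first, _order=order)
    # stable: among equal |M| keep the earliest row
    idx = (
        df.sort_values(["_absM", "_order"], ascending=[False, True], kind="stable")
        .drop_duplicates("gene_symbol", keep="first")
        .sort_values("_order")
        .index
    )
    return table.loc[idx].reset_index(drop=True)
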