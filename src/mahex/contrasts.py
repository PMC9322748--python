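"""Replicate-free pairwise contrasts and their (A, M) representation.

With pooled single-channel chips and no replicates, a contrast between
two samples reduces to the per-probe-set log ratio::

    M = e_treated - e_reference        (log2 fold change)
    A = (e_treated + e_reference) / 2  (average log2 intensity)

"X vs. Y" maps to M = X - Y on the log2 scale, so positive M means
higher expression in the treated (first-named) sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ContrastDef", "default_contrasts", "compute_contrast"]


@dataclass(frozen=True)
class ContrastDef:
    contrast_id: int
    treated_sample: str
    reference_sample: str

    def __post_init__(self) -> None:
        if self.treated_sample == self.reference_sample:
            raise ValueError("treated and reference samples must differ")

    @property
    def label(self) -> str:
        return f"{self.treated_sample} vs. {self.reference_sample}"


#: The seven ordered sample comparisons of the six-chip design:
#: LPS effect within tumor enteroids (1), IBD enteroids (2) and IBD
#: colonoids (3); anatomical and microenvironment comparisons between
#: controls (4, 5) and between LPS-treated groups (6, 7).
_DEFAULT_PAIRS = ((2, 1), (4, 3), (6, 5), (5, 3), (3, 1), (6, 4), (4, 2))


def default_contrasts() -> list[ContrastDef]:
    """The seven standard ordered sample pairs of the six-chip design."""
    return [
        ContrastDef(i + 1, f"Sample-{t}", f"Sample-{r}")
        for i, (t, r) in enumerate(_DEFAULT_PAIRS)
    ]


def compute_contrast(expr: pd.DataFrame, cdef: ContrastDef) -> pd.DataFrame:
    """Compute per-probe-set (A, M) for one ordered sample pair.

    Parameters
    ----------
    expr : pandas.DataFrame
        Log2 expression matrix with ``probeset_id`` (and optionally
        ``gene_symbol``) plus one column per sample.
    cdef : ContrastDef
        Ordered pair; its samples must be columns of ``expr``.

    Returns
    -------
    pandas.DataFrame with columns ``probeset_id``, ``gene_symbol`` (if
    present), ``A`` and ``M``, one row per probe set.
    """
    for s in (cdef.treated_sample, cdef.reference_sample):
        if s not in expr.columns:
            raise KeyError(f"sample {s!r} missing from expression matrix")
    e_t = expr[cdef.treated_sample].to_numpy(float)
    e_r = expr[cdef.reference_sample].to_numpy(float)
    if not (np.isfinite(e_t).all() and np.isfinite(e_r).all()):
        raise ValueError("expression values must be finite")
    out = {"probeset_id": expr["probeset_id"].to_numpy()}
    if "gene_symbol" in expr.columns:
        out["gene_symbol"] = expr["gene_symbol"].to_numpy()
    out["A"] = (e_t + e_r) / 2.0
    out["M"] = e_t - e_r
    return pd.DataFrame(out)
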