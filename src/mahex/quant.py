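"""Small quantitative summaries: delta-delta-Ct relative qPCR
quantification, the pooled-variance two-sample t-test, and functional
category percentage tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddct_fold_change",
    "students_t",
    "TTestResult",
    "category_percentages",
]


def ddct_fold_change(ct: pd.DataFrame) -> float:
    """Relative expression fold change by the delta-delta-Ct method.

    ``ct`` holds one row per qPCR reaction with columns ``group``
    ({"control", "treated"}), ``target_ct`` and ``reference_ct``
    (cycle thresholds of the gene of interest and the normalizer,
    e.g. GAPDH).  Technical replicates are averaged within group::

        dCt_g  = mean(target_ct - reference_ct)   per group
        ddCt   = dCt_treated - dCt_control
        fold   = 2 ** (-ddCt)

    A fold change of 1 means no relative change; lower target Ct in
    the treated group (earlier amplification) gives fold > 1.
    """
    groups = set(ct["group"])
    if not {"control", "treated"} <= groups:
        raise ValueError("Ct table must contain both control and treated groups")
    if (ct[["target_ct", "reference_ct"]].to_numpy(float) <= 0).any():
        raise ValueError("cycle thresholds must be positive")
    dct = (
        (ct["target_ct"] - ct["reference_ct"])
        .groupby(ct["group"])
        .mean()
    )
    ddct = dct["treated"] - dct["control"]
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    flagged: bool = False  # degenerate zero-variance input with unequal means


def students_t(group1, group2) -> TTestResult:
    """Unpaired two-tailed Student's t-test (pooled equal variance).

    Degenerate inputs: zero pooled variance with equal means returns
    t = 0, p = 1; zero variance with unequal means returns an infinite
    t with p = 0, flagged.
    """
    x = np.asarray(group1, float)
    y = np.asarray(group2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, df)
        return TTestResult(float(np.sign(diff)) * np.inf, 0.0, df, flagged=True)
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), df)


def category_percentages(genes, categories: pd.DataFrame) -> pd.DataFrame:
    """Per-category gene counts and rounded percentages for one GO
    sub-tree.

    ``genes`` is the gene set of interest; ``categories`` a two-column
    frame (``category``, ``gene``) listing category membership.  The
    percentage denominator is the total number of category assignments
    within the sub-tree (a gene appearing in k categories contributes
    k), so percentages over the sub-tree sum to ~100.  Rounding is to
    the nearest integer, ties half up.
    """
    genes = set(genes)
    hits = categories[categories["gene"].isin(genes)]
    counts = hits.groupby("category", sort=False).size()
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no category assignments for the given gene set")
    out = counts.rename("count").reset_index()
    out["percent"] = np.floor(100.0 * out["count"] / total + 0.5).astype(int)
    return out.sort_values(["count", "category"], ascending=[False, True]).reset_index(
        drop=True
    )
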