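"""Hexagonal binning of the MA plane and low-density probe selection.

An MA plot of a replicate-free contrast is a cone-shaped cloud: most
probe sets sit near M = 0 and the spread of M shrinks as the average
intensity A grows.  Binning the plane on a hexagon lattice turns the
cloud into per-hexagon occupancy counts; probe sets falling in
sparsely occupied hexagons are the points on the edge of the cone —
the most differentially expressed given their intensity.  Selection
accumulates hexagons from the least to the most occupied until a fixed
number of probes (default 500) is reached, which makes the output size
independent of the absolute magnitude of M.

Lattice construction: the (A, M) extents are mapped to the unit
square, so hexagons are regular in the scaled plane regardless of the
data units.  Pointy-top hexagons are laid out as two offset
rectangular grids (the standard hexbin construction); ``gridsize``
hexagons span the A extent.  A point belongs to the hexagon whose
center is nearest in the unit-square metric; exact ties go to the
lexicographically smaller (row, col) lattice coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HexGrid",
    "hex_assign",
    "bin_counts",
    "select_low_density",
    "summarize_up_down",
]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class HexGrid:
    """Regular pointy-top hexagon lattice over an (A, M) extent."""

    gridsize: int = 50
    extent: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.gridsize < 2:
            raise ValueError("gridsize must be >= 2")
        a0, a1, m0, m1 = self.extent
        if not (np.isfinite(self.extent).all() and a1 > a0 and m1 > m0):
            raise ValueError("extent must be finite with positive spans")

    @classmethod
    def from_points(cls, A: np.ndarray, M: np.ndarray, gridsize: int = 50) -> "HexGrid":
        A = np.asarray(A, float)
        M = np.asarray(M, float)
        if not (np.isfinite(A).all() and np.isfinite(M).all()):
            raise ValueError("points must be finite")
        a0, a1 = float(A.min()), float(A.max())
        m0, m1 = float(M.min()), float(M.max())
        # degenerate span: widen symmetrically so the extent covers the data
        if a1 <= a0:
            a0, a1 = a0 - 0.5, a1 + 0.5
        if m1 <= m0:
            m0, m1 = m0 - 0.5, m1 + 0.5
        return cls(gridsize=gridsize, extent=(a0, a1, m0, m1))

    # lattice geometry in unit-square coordinates ------------------------
    @property
    def _width(self) -> float:
        return 1.0 / self.gridsize        # horizontal center spacing

    @property
    def _row_height(self) -> float:
        return _SQRT3 / (2.0 * self.gridsize)  # vertical row spacing (1.5 r)

    def scale(self, A: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a0, a1, m0, m1 = self.extent
        u = np.clip((np.asarray(A, float) - a0) / (a1 - a0), 0.0, 1.0)
        v = np.clip((np.asarray(M, float) - m0) / (m1 - m0), 0.0, 1.0)
        return u, v

    def centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unit-square center of the hexagon at lattice (row, col)."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        cu = (cols + 0.5 * (rows % 2)) * self._width
        cv = rows * self._row_height
        return cu, cv


def hex_assign(A: np.ndarray, M: np.ndarray, grid: HexGrid) -> np.ndarray:
    """Assign points to hexagons; returns an (n, 2) array of (row, col).

    Each point gets the hexagon whose center is nearest in the
    unit-square metric, ties broken toward the lexicographically
    smaller (row, col).  Points outside the extent are clamped to the
    boundary first.
    """
    A = np.atleast_1d(np.asarray(A, float))
    M = np.atleast_1d(np.asarray(M, float))
    if not (np.isfinite(A).all() and np.isfinite(M).all()):
        raise ValueError("points must be finite")
    u, v = grid.scale(A, M)
    w, h = grid._width, grid._row_height

    j0 = np.floor(v / h).astype(np.int64)
    cand_rows = np.stack([j0 - 1, j0, j0 + 1, j0 - 1, j0, j0 + 1], axis=1)
    # for each candidate row, the two nearest columns
    off = 0.5 * (cand_rows % 2)
    i_low = np.floor(u[:, None] / w - off).astype(np.int64)
    cand_cols = np.concatenate([i_low[:, :3], i_low[:, 3:] + 1], axis=1)

    cu, cv = grid.centers(cand_rows, cand_cols)
    d2 = (u[:, None] - cu) ** 2 + (v[:, None] - cv) ** 2
    dmin = d2.min(axis=1, keepdims=True)
    tied = d2 <= dmin + 1e-15
    # among tied candidates prefer the smallest (row, col)
    big = np.int64(1) << 32
    key = cand_rows * big + cand_cols
    key = np.where(tied, key, np.iinfo(np.int64).max)
    pick = key.argmin(axis=1)
    idx = np.arange(len(u))
    return np.stack([cand_rows[idx, pick], cand_cols[idx, pick]], axis=1)


def bin_counts(ma: pd.DataFrame, grid: HexGrid | None = None, gridsize: int = 50) -> pd.DataFrame:
    """Per-hexagon occupancy counts for an (A, M) table.

    Returns a frame with ``row, col, count`` summing to the number of
    points; the grid defaults to one fitted to the data extent.
    """
    if len(ma) == 0:
        raise ValueError("MA table is empty")
    A = ma["A"].to_numpy(float)
    M = ma["M"].to_numpy(float)
    if grid is None:
        grid = HexGrid.from_points(A, M, gridsize=gridsize)
    cells = hex_assign(A, M, grid)
    frame = pd.DataFrame({"row": cells[:, 0], "col": cells[:, 1]})
    counts = (
        frame.value_counts(["row", "col"]).rename("count").reset_index()
    )
    return counts.sort_values(["row", "col"]).reset_index(drop=True)


@dataclass
class HexSelection:
    """Result of a low-density selection on one contrast."""

    grid: HexGrid
    counts: pd.DataFrame                # row, col, count
    selected: pd.DataFrame              # probeset_id, [gene_symbol], A, M, direction, row, col, hex_count
    target_n: int
    truncated: bool                     # fewer points than target_n
    members: pd.DataFrame = field(repr=False, default=None)  # all points with row/col

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select_low_density(
    ma: pd.DataFrame,
    grid: HexGrid | None = None,
    target_n: int = 500,
    gridsize: int = 50,
) -> HexSelection:
    """Select the probes in the least occupied hexagons of the MA plane.

    Hexagons are ranked by ascending occupancy and whole occupancy
    tiers (all hexagons sharing a count) are accumulated until at least
    ``target_n`` probes are gathered; within the final tier probes are
    ranked by descending |M| (then probeset_id) and the selection is
    truncated to exactly ``target_n``.  Selected probes are labelled
    ``up`` (M > 0), ``down`` (M < 0) or ``unchanged`` (M = 0).

    If the input holds fewer than ``target_n`` points, all points are
    returned and the selection is flagged as truncated.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    if len(ma) == 0:
        raise ValueError("MA table is empty")
    A = ma["A"].to_numpy(float)
    M = ma["M"].to_numpy(float)
    if grid is None:
        grid = HexGrid.from_points(A, M, gridsize=gridsize)
    cells = hex_assign(A, M, grid)

    pts = ma.copy().reset_index(drop=True)
    pts["row"] = cells[:, 0]
    pts["col"] = cells[:, 1]
    counts = (
        pts.value_counts(["row", "col"]).rename("hex_count").reset_index()
    )
    pts = pts.merge(counts, on=["row", "col"], how="left")

    truncated = len(pts) < target_n
    if truncated:
        chosen = pts
    else:
        tiers = np.sort(counts["hex_count"].unique())
        cum = 0
        keep_tiers = []
        final_tier = None
        for t in tiers:
            tier_total = int(pts["hex_count"].eq(t).sum())
            if cum + tier_total >= target_n:
                final_tier = t
                break
            keep_tiers.append(t)
            cum += tier_total
        inner = pts[pts["hex_count"].isin(keep_tiers)]
        tier_pts = pts[pts["hex_count"] == final_tier].copy()
        tier_pts["_absM"] = tier_pts["M"].abs()
        tier_pts = tier_pts.sort_values(
            ["_absM", "probeset_id"], ascending=[False, True], kind="stable"
        ).drop(columns="_absM")
        chosen = pd.concat([inner, tier_pts.head(target_n - cum)], ignore_index=True)

    chosen = chosen.copy()
    chosen["direction"] = np.select(
        [chosen["M"] > 0, chosen["M"] < 0], ["up", "down"], default="unchanged"
    )
    counts_sorted = counts.sort_values(["row", "col"]).reset_index(drop=True)
    counts_sorted = counts_sorted.rename(columns={"hex_count": "count"})
    return HexSelection(
        grid=grid,
        counts=counts_sorted,
        selected=chosen.reset_index(drop=True),
        target_n=target_n,
        truncated=truncated,
        members=pts,
    )


def summarize_up_down(selection: HexSelection) -> dict:
    """Total selected probes and the rounded up/down percentage split.

    Probes with M = 0 carry direction ``unchanged`` and are excluded
    from the percentage denominator (their count is reported).
    Percentages are rounded to the nearest integer, half away from
    zero, so up + down = 100 +/- 1.
    """
    sel = selection.selected
    if len(sel) == 0:
        raise ValueError("selection is empty")
    n_up = int((sel["direction"] == "up").sum())
    n_down = int((sel["direction"] == "down").sum())
    n_unchanged = int((sel["direction"] == "unchanged").sum())
    denom = n_up + n_down
    pct = lambda k: int(np.floor(100.0 * k / denom + 0.5)) if denom else 0
    return {
        "total": len(sel),
        "pct_up": pct(n_up),
        "pct_down": pct(n_down),
        "n_up": n_up,
        "n_down": n_down,
        "n_unchanged": n_unchanged,
    }
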