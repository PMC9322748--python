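"""Probe-level preprocessing: background correction, quantile
normalization, median-polish summarization and chip QC diagnostics.

The chain mirrors the RMA family for single-channel oligonucleotide
arrays: an additive-background correction (normal + exponential
convolution by default), quantile normalization across chips, log2
transform, and per-probe-set median polish whose per-sample column
effects become the probe-set expression values.  Chip quality is
summarised by NUSE (normalized unscaled standard errors of the
median-polish fit) and by the slope of mean log2 intensity against
probe position (RNA degradation profile).

All logarithms are base 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "META_COLUMNS",
    "sample_columns",
    "background_correct",
    "normexp_fit",
    "normexp_signal",
    "quantile_normalize",
    "summarize_median_polish",
    "MedianPolishFit",
    "compute_nuse",
    "degradation_profile",
    "rma",
]

#: Annotation columns of a probe matrix; every other column is a sample.
META_COLUMNS = ("probe_id", "probeset_id", "gene_symbol", "position_index", "gc_content")

_EPS = 1e-10


def sample_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# background correction


def _normexp_nll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    a = x - mu - sigma**2 / alpha
    ll = (
        -np.log(alpha)
        + (mu - x) / alpha
        + sigma**2 / (2 * alpha**2)
        + norm.logcdf(a / sigma)
    )
    return -float(ll.sum())


def normexp_fit(x: np.ndarray, max_points: int = 20_000) -> tuple[float, float, float]:
    """Maximum-likelihood estimates (mu, sigma, alpha) of the normal
    (background) + exponential (signal) convolution for one sample.

    The likelihood is evaluated on evenly spaced order statistics when
    the column exceeds ``max_points`` values (deterministic, keeps the
    empirical distribution).  A constant column returns a degenerate
    fit whose posterior mean reproduces the constant.
    """
    x = np.asarray(x, float)
    if x.var() == 0:
        return 0.0, np.sqrt(_EPS), float(max(x[0], _EPS))
    xs = np.sort(x)
    if len(xs) > max_points:
        idx = np.linspace(0, len(xs) - 1, max_points).round().astype(int)
        xs = xs[idx]
    q05, q25 = np.quantile(xs, [0.05, 0.25])
    mu0 = q25
    sigma0 = max(float(np.std(xs[xs <= q25])), (q25 - q05) / 2, _EPS)
    alpha0 = max(float(xs.mean() - mu0), sigma0)
    from scipy.optimize import minimize

    res = minimize(
        _normexp_nll,
        x0=np.array([mu0, np.log(sigma0), np.log(alpha0)]),
        args=(xs,),
        method="Nelder-Mead",
        options={"maxiter": 500, "xatol": 1e-6, "fatol": 1e-6},
    )
    mu, log_sigma, log_alpha = res.x
    return float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha))


def normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Posterior mean of the exponential signal given observed intensity.

    E[S | X = x] = a + sigma * phi(a / sigma) / Phi(a / sigma) with
    a = x - mu - sigma^2 / alpha, phi/Phi the standard normal density
    and CDF.  Strictly positive and monotone increasing in x.
    """
    x = np.asarray(x, float)
    a = x - mu - sigma**2 / alpha
    z = a / sigma
    signal = a + sigma * np.exp(norm.logpdf(z) - norm.logcdf(z))
    return np.maximum(signal, _EPS)


def _shift_log_background(col: np.ndarray) -> float:
    # Half the column minimum: scale-equivariant (b(kx) = k b(x)), so
    # a global rescaling of raw intensities shifts log2 expression by
    # exactly the log of the factor; corrected values stay positive.
    return 0.5 * float(col.min())


def background_correct(
    matrix: pd.DataFrame,
    method: str = "normexp",
    offset: float = 0.0,
    background: float | None = None,
) -> pd.DataFrame:
    """Background-correct each sample column of a probe matrix.

    method : {"shift-log", "normexp", "gc-stratified"}
        ``shift-log`` subtracts a per-sample background (half the
        column minimum unless ``background`` is given; a background of
        zero leaves the data untouched).  ``normexp`` replaces
        intensities by the posterior mean signal of the normal +
        exponential convolution.  ``gc-stratified`` applies the
        shift-log estimate within GC-content quintiles (requires a
        ``gc_content`` column).
    offset : float
        Constant added to every corrected intensity, the customary
        damping of log-ratio variance at low intensities (0 leaves the
        correction untouched; 16-50 is the customary range).
    background : float, optional
        Explicit background level for the shift-log family, replacing
        the per-sample estimate.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    cols = sample_columns(matrix)
    if not cols:
        raise ValueError("probe matrix has no sample columns")
    vals = matrix[cols].to_numpy(float)
    if (vals <= 0).any():
        raise ValueError("probe intensities must be strictly positive")
    out = matrix.copy()
    if method == "shift-log":
        for j, c in enumerate(cols):
            b = background if background is not None else _shift_log_background(
                vals[:, j])
            if b >= vals[:, j].min():
                raise ValueError("background must sit below the column minimum")
            out[c] = vals[:, j] - b
    elif method == "normexp":
        for j, c in enumerate(cols):
            out[c] = normexp_signal(vals[:, j], *normexp_fit(vals[:, j]))
    elif method == "gc-stratified":
        if "gc_content" not in matrix.columns:
            raise ValueError("gc-stratified correction requires a gc_content column")
        gc = matrix["gc_content"].to_numpy(float)
        edges = np.quantile(gc, np.linspace(0, 1, 6))
        edges[0], edges[-1] = -np.inf, np.inf
        stratum = np.searchsorted(edges, gc, side="right") - 1
        for j, c in enumerate(cols):
            corrected = vals[:, j].copy()
            for s in np.unique(stratum):
                mask = stratum == s
                b = (background if background is not None
                     else _shift_log_background(vals[mask, j]))
                corrected[mask] -= b
            out[c] = corrected
    else:
        raise ValueError(f"unknown background correction method {method!r}")
    if offset:
        for c in cols:
            out[c] = out[c] + offset
    return out


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common distribution of
    across-chip row means of the sorted columns.

    Rank order within each column is preserved; tied values receive the
    mean of the reference values across their tied ranks.
    """
    cols = sample_columns(matrix)
    if not cols:
        raise ValueError("probe matrix has no sample columns")
    X = matrix[cols].to_numpy(float)
    if X.shape[0] == 0:
        raise ValueError("probe matrix is empty")
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = matrix.copy()
    for j, c in enumerate(cols):
        o = order[:, j]
        sorted_col = X[o, j]
        new_group = np.r_[True, sorted_col[1:] != sorted_col[:-1]]
        grp = np.cumsum(new_group) - 1
        grp_mean = np.bincount(grp, weights=reference) / np.bincount(grp)
        normalized = np.empty_like(sorted_col)
        normalized[o] = grp_mean[grp]
        out[c] = normalized
    return out


# ---------------------------------------------------------------------------
# median-polish summarization


@dataclass
class MedianPolishFit:
    """Residuals and bookkeeping of a median-polish summarization."""

    probeset_ids: np.ndarray          # (G,)
    sample_names: list[str]
    residuals: np.ndarray             # flat (n_probes, S), probe rows grouped
    probes_per_set: np.ndarray        # (G,)
    group_of_probe: np.ndarray        # (n_probes,) index into probeset_ids


def _polish_blocks(blocks: np.ndarray, max_iter: int, tol: float):
    """Vectorised Tukey median polish on a stack of equally sized
    (probes x samples) blocks.  Row (probe) sweep precedes the column
    (sample) sweep; even-length medians are midpoints of the middle
    pair (numpy convention)."""
    resid = blocks.astype(float).copy()
    G, P, S = resid.shape
    overall = np.zeros(G)
    row = np.zeros((G, P))
    col = np.zeros((G, S))
    for _ in range(max_iter):
        rm = np.median(resid, axis=2)
        resid -= rm[:, :, None]
        row += rm
        rc = np.median(row, axis=1)
        row -= rc[:, None]
        overall += rc
        cm = np.median(resid, axis=1)
        resid -= cm[:, None, :]
        col += cm
        cc = np.median(col, axis=1)
        col -= cc[:, None]
        overall += cc
        if max(np.abs(rm).max(initial=0.0), np.abs(cm).max(initial=0.0)) < tol:
            break
    return overall, row, col, resid


def summarize_median_polish(
    matrix: pd.DataFrame,
    max_iter: int = 10,
    tol: float = 0.01,
) -> tuple[pd.DataFrame, MedianPolishFit]:
    """Summarize log2 probe intensities into per-probe-set expression.

    ``matrix`` must hold log2-transformed, background-corrected
    intensities.  Each probe set's probes-by-samples block is median
    polished; the probe-set expression for a sample is the grand effect
    plus that sample's column effect.

    Returns the expression matrix (``probeset_id, gene_symbol,``
    one column per sample) and the fit residuals for NUSE.
    """
    cols = sample_columns(matrix)
    if not cols or len(matrix) == 0:
        raise ValueError("probe matrix is empty")
    if max_iter < 1 or tol <= 0:
        raise ValueError("max_iter must be >= 1 and tol positive")

    # stable sort by probe set keeps within-set probe order
    m = matrix.sort_values("probeset_id", kind="stable").reset_index(drop=True)
    ids = m["probeset_id"].to_numpy()
    new_set = np.r_[True, ids[1:] != ids[:-1]]
    group = np.cumsum(new_set) - 1
    probeset_ids = ids[new_set]
    sizes = np.bincount(group)
    if (sizes == 0).any():
        raise ValueError("probe set with zero probes")
    X = m[cols].to_numpy(float)
    S = len(cols)
    G = len(probeset_ids)

    if (sizes == sizes[0]).all():
        blocks = X.reshape(G, sizes[0], S)
        overall, _row, col, resid3 = _polish_blocks(blocks, max_iter, tol)
        expr_vals = overall[:, None] + col
        resid = resid3.reshape(-1, S)
    else:
        expr_vals = np.empty((G, S))
        resid = np.empty_like(X)
        starts = np.r_[0, np.cumsum(sizes)]
        for g in range(G):
            sl = slice(starts[g], starts[g + 1])
            o, _r, c, rs = _polish_blocks(X[sl][None, :, :], max_iter, tol)
            expr_vals[g] = o[0] + c[0]
            resid[sl] = rs[0]

    expr = pd.DataFrame({"probeset_id": probeset_ids})
    if "gene_symbol" in m.columns:
        expr["gene_symbol"] = m["gene_symbol"].to_numpy()[new_set]
    for j, c in enumerate(cols):
        expr[c] = expr_vals[:, j]
    fit = MedianPolishFit(
        probeset_ids=probeset_ids,
        sample_names=list(cols),
        residuals=resid,
        probes_per_set=sizes,
        group_of_probe=group,
    )
    return expr, fit


# ---------------------------------------------------------------------------
# QC diagnostics


def compute_nuse(fit: MedianPolishFit) -> tuple[pd.DataFrame, pd.Series]:
    """Normalized unscaled standard errors from median-polish residuals.

    For probe set g and sample j the unscaled SE is the MAD-based
    residual scale divided by sqrt(probes in set); NUSE divides it by
    the median SE of that probe set across samples.  Chips whose NUSE
    median sits well above 1 are flagged as poor.  A single-sample fit
    (or an exactly additive probe set, zero residual scale) has NUSE 1
    by convention.
    """
    absr = pd.DataFrame(
        np.abs(fit.residuals), columns=fit.sample_names
    ).groupby(fit.group_of_probe)
    scale = 1.4826 * absr.median().to_numpy()  # (G, S)
    se = scale / np.sqrt(fit.probes_per_set)[:, None]
    med = np.median(se, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        nuse = np.where(med > 0, se / med, 1.0)
    if len(fit.sample_names) == 1:
        nuse = np.ones_like(nuse)
    table = pd.DataFrame(nuse, columns=fit.sample_names)
    table.insert(0, "probeset_id", fit.probeset_ids)
    per_chip = table[fit.sample_names].median()
    per_chip.name = "nuse_median"
    return table, per_chip


def degradation_profile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Least-squares slope of mean log2 intensity against probe
    position (5'->3') for each sample; an RNA degradation summary.

    Returns a frame with ``sample``, ``slope`` and a ``flagged`` column
    set when the slope is undefined (all probes at one position).
    """
    if "position_index" not in matrix.columns:
        raise ValueError("degradation profile requires a position_index column")
    cols = sample_columns(matrix)
    pos = matrix["position_index"].to_numpy(float)
    vals = np.log2(matrix[cols].to_numpy(float))
    positions = np.unique(pos)
    rows = []
    if len(positions) < 2:
        for c in cols:
            rows.append({"sample": c, "slope": np.nan, "flagged": True})
        return pd.DataFrame(rows)
    means = np.empty((len(positions), len(cols)))
    for i, p in enumerate(positions):
        means[i] = vals[pos == p].mean(axis=0)
    slope = np.polyfit(positions, means, deg=1)[0]
    for j, c in enumerate(cols):
        rows.append({"sample": c, "slope": float(slope[j]), "flagged": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convenience chain


def rma(
    matrix: pd.DataFrame,
    background: str = "normexp",
    offset: float = 50.0,
    normalize: bool = True,
    max_iter: int = 10,
    tol: float = 0.01,
) -> tuple[pd.DataFrame, MedianPolishFit, dict]:
    """Full preprocessing chain: background correction with a
    low-intensity damping offset, optional quantile normalization,
    log2 transform and median-polish summarization.
    Returns (expression matrix, fit, QC report dict)."""
    corrected = background_correct(matrix, method=background, offset=offset)
    if normalize:
        corrected = quantile_normalize(corrected)
    logged = corrected.copy()
    for c in sample_columns(corrected):
        logged[c] = np.log2(corrected[c].to_numpy(float))
    expr, fit = summarize_median_polish(logged, max_iter=max_iter, tol=tol)
    _nuse_table, nuse_medians = compute_nuse(fit)
    qc: dict = {"nuse_median": {k: float(v) for k, v in nuse_medians.items()}}
    if "position_index" in matrix.columns:
        deg = degradation_profile(matrix)
        qc["degradation_slope"] = {
            r["sample"]: (None if r["flagged"] else float(r["slope"]))
            for r in deg.to_dict("records")
        }
    return expr, fit, qc
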