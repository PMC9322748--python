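"""Synthetic single-channel chip data with planted differential expression.

The generator emulates a six-sample canine expression chip experiment:
probe-level optical intensities for ``n_probesets`` probe sets, each
interrogated by ``probes_per_set`` probes, hybridised on ``n_samples``
single-channel chips (no replicates).  A configurable fraction of probe
sets receives a planted log2 expression shift in the treated member of
each pairwise contrast, so every downstream stage (background
correction, normalization, summarization, MA contrasts, low-density
selection) can be tested against a known truth table.

Intensity model (per probe p of probe set g on sample j)::

    I_pgj = B_pgj + 2 ** (mu_g + shift_gj + eps_pgj)

where ``B`` is exponential optical background with mean
``background_mean``, ``mu_g`` is a per-probe-set baseline log2
abundance drawn once and shared across samples, ``shift_gj`` is the
accumulated planted log2 shift for sample j, and
``eps ~ Normal(0, noise_sd)`` is log-scale measurement noise.  This is
the additive background + log-normal signal convolution that RMA-style
background correction assumes.

Baseline abundance is a right-skewed two-component mixture, as on real
chips: a majority of probe sets unexpressed in any one tissue (piled
near the optical floor) and an expressed minority spread over several
log2 units above it.  Planted differential expression is restricted to
probe sets whose shifted signal stays above the background mean — a
shift on a sub-background transcript is unobservable by construction
and would make the truth table unrealizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import ContrastDef, default_contrasts

__all__ = ["SimConfig", "generate_chips"]

# Table 2 sample roles: tumor enteroids (1,2), IBD enteroids (3,4),
# IBD colonoids (5,6); odd = control, even = LPS treated.
SAMPLE_NAMES = tuple(f"Sample-{i}" for i in range(1, 7))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic chip experiment.

    Defaults mirror the study conditions of the emulated experiment:
    a >42,800 probe-set canine genome chip, six single-channel samples,
    seven pairwise contrasts, ~250 planted differential probe sets per
    contrast with a 2.0 log2-unit shift over 0.2 log2 units of noise.
    """

    n_probesets: int = 42_800
    probes_per_set: int = 11
    n_samples: int = 6
    de_fraction: float = 0.006
    effect_size: float = 2.0
    noise_sd: float = 0.2
    background_mean: float = 100.0
    expressed_fraction: float = 0.4
    mu_mean: float = 10.0
    mu_sd: float = 1.5
    seed: int = 0
    emit_gc: bool = False
    contrasts: tuple[ContrastDef, ...] = field(
        default_factory=lambda: tuple(default_contrasts())
    )

    def __post_init__(self) -> None:
        if self.n_probesets < 1 or self.probes_per_set < 1 or self.n_samples < 1:
            raise ValueError("chip dimensions must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect_size < 0.0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ValueError("expressed_fraction must lie in [0, 1]")
        if self.background_mean < 0.0:
            raise ValueError("background_mean must be non-negative")
        for c in self.contrasts:
            for s in (c.treated_sample, c.reference_sample):
                idx = _sample_index(s)
                if idx >= self.n_samples:
                    raise ValueError(f"contrast references missing sample {s!r}")

    @property
    def sample_names(self) -> list[str]:
        return [f"Sample-{i}" for i in range(1, self.n_samples + 1)]


def _sample_index(name: str) -> int:
    try:
        return int(name.rsplit("-", 1)[1]) - 1
    except (IndexError, ValueError) as exc:
        raise ValueError(f"unrecognised sample name {name!r}") from exc


def generate_chips(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate probe-level intensities and the matching truth table.

    Returns
    -------
    probe_matrix : pandas.DataFrame
        Columns ``probe_id, probeset_id, gene_symbol, position_index``
        (plus ``gc_content`` when ``config.emit_gc``) and one intensity
        column per sample.  ``n_probesets * probes_per_set`` rows, all
        intensities strictly positive.
    truth : pandas.DataFrame
        One row per (probeset_id, contrast_id) with columns
        ``probeset_id, contrast_id, true_direction, true_log2_shift``;
        direction is ``up``/``down``/``null``.
    """
    rng = np.random.default_rng(config.seed)
    G, P, S = config.n_probesets, config.probes_per_set, config.n_samples

    probeset_ids = np.array([f"SimSet.{g:06d}_at" for g in range(G)])
    gene_symbols = np.array([f"GENE{g:06d}" for g in range(G)])

    # Baseline log2 abundance: a right-skewed mixture as on real
    # chips — most probe sets are unexpressed in any one tissue and
    # pile up near the optical floor; the expressed minority spreads
    # over several log2 units above it.
    expressed = rng.random(G) < config.expressed_fraction
    floor_mu = (
        np.log2(config.background_mean) - 1.5 if config.background_mean > 0 else 1.0
    )
    mu = np.where(
        expressed,
        rng.normal(config.mu_mean, config.mu_sd, size=G),
        rng.normal(floor_mu, 1.0, size=G),
    )

    # Ground truth must be realizable by the chip: a planted shift on a
    # transcript whose shifted signal sits below the optical floor is
    # unobservable by construction, so differential probe sets are
    # drawn from those whose signal stays above the background mean
    # even after a downward shift.
    if config.background_mean > 0:
        floor = np.log2(config.background_mean) + config.effect_size
    else:
        floor = -np.inf
    eligible = np.flatnonzero(mu >= floor)

    # Planted shifts accumulate per (probe set, treated sample); each
    # contrast plants independently so overlapping contrasts may share
    # differential probe sets.
    shift = np.zeros((G, S))
    truth_frames = []
    n_de = int(round(config.de_fraction * G))
    for cdef in config.contrasts:
        t_idx = _sample_index(cdef.treated_sample)
        if n_de == 0:
            chosen = np.array([], int)
        elif n_de <= len(eligible):
            chosen = rng.choice(eligible, size=n_de, replace=False)
        else:
            rest = np.setdiff1d(np.arange(G), eligible)
            extra = rng.choice(rest, size=n_de - len(eligible), replace=False)
            chosen = np.concatenate([eligible, extra])
        signs = rng.choice([1.0, -1.0], size=n_de)
        direction = np.full(G, "null", dtype=object)
        d_shift = np.zeros(G)
        if n_de:
            d_shift[chosen] = signs * config.effect_size
            direction[chosen] = np.where(signs > 0, "up", "down")
            shift[chosen, t_idx] += signs * config.effect_size
        truth_frames.append(
            pd.DataFrame(
                {
                    "probeset_id": probeset_ids,
                    "contrast_id": cdef.contrast_id,
                    "true_direction": direction,
                    "true_log2_shift": d_shift,
                }
            )
        )
    truth = pd.concat(truth_frames, ignore_index=True)

    # Probe-level log2 signal: every probe of a probe set shares mu and
    # the planted shift; noise is independent per probe and sample.
    log2_signal = (
        mu[:, None, None]
        + shift[:, None, :]
        + rng.normal(0.0, config.noise_sd, size=(G, P, S))
    )
    background = rng.exponential(config.background_mean, size=(G, P, S))
    intensities = background + np.exp2(log2_signal)

    probe_matrix = pd.DataFrame(
        {
            "probe_id": [
                f"{ps}:p{p}" for ps in probeset_ids for p in range(P)
            ],
            "probeset_id": np.repeat(probeset_ids, P),
            "gene_symbol": np.repeat(gene_symbols, P),
            "position_index": np.tile(np.arange(P), G),
        }
    )
    if config.emit_gc:
        probe_matrix["gc_content"] = rng.uniform(0.3, 0.7, size=G * P)
    flat = intensities.reshape(G * P, S)
    for j, name in enumerate(config.sample_names):
        probe_matrix[name] = flat[:, j]
    return probe_matrix, truth
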