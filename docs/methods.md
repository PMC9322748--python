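# Methods

This note documents the models, algorithms, defaults and design
choices behind `mahex`, and what the synthetic-data tests do and do
not establish about real chips.

## Study design

Six single-channel chips, one per condition, with no replicates:
tumor-adjacent enteroids (control/LPS = Sample-1/2), IBD enteroids
(Sample-3/4) and IBD colonoids (Sample-5/6).  Seven ordered contrasts
are standard: the three LPS effects (2 vs 1, 4 vs 3, 6 vs 5), two
control-side comparisons (5 vs 3, 3 vs 1) and two treated-side
comparisons (6 vs 4, 4 vs 2).  "X vs Y" maps to `M = X − Y` on the
log₂ scale, so positive M means higher under the first-named
condition.  Without replicates no variance can be estimated per gene,
which rules out moderated statistics; the analysis is built entirely
from per-probe-set log-ratios.

## Synthetic chips

The generator emulates what the analysis assumes about probe-level
data.  Per probe p of probe set g on sample j:

    I_pgj = B_pgj + 2^(mu_g + shift_gj + eps_pgj)

* `B ~ Exponential(background_mean)` — additive optical background,
  default mean 100 (a typical single-channel floor).
* `mu_g` — baseline log₂ abundance, drawn once per probe set and
  shared by its probes and samples.  It is a right-skewed
  two-component mixture: with probability `1 − expressed_fraction`
  (default 0.6) the probe set is unexpressed and `mu ~
  N(log2(background_mean) − 1.5, 1)`, i.e. piled just under the
  optical floor; otherwise `mu ~ N(10, 1.5)`, several log₂ units
  above it.  A symmetric abundance distribution would make *both*
  extremes of the A axis sparse, which real arrays do not show — the
  low-A end of a real MA plot is the dense thick end of the cone.
* `shift_gj` — the planted differential signal: per contrast,
  `round(de_fraction × n_probesets)` probe sets (default 0.006 ×
  42,800 ≈ 257) receive a ±`effect_size` shift (default 2.0 log₂
  units, equiprobable sign) in the contrast's treated sample.  All
  probes of a planted set share the shift.  Eligibility is restricted
  to probe sets with `mu ≥ log2(background_mean) + effect_size`: a
  downward shift on a sub-background transcript cannot alter the
  measured intensity, so a truth table containing it would be
  unrealizable by construction.
* `eps ~ N(0, noise_sd)` — log-scale measurement noise, default 0.2.

Contrasts share samples, so a shift planted in Sample-4 for contrast
2 (4 vs 3) necessarily also appears in contrast 7 (4 vs 2).  This is
deliberate (it produces the overlapping gene sets the concordance
stage classifies) but it means per-contrast recall in a seven-contrast
run is diluted: each contrast carries roughly three times more genuine
outliers than selection slots.  Recovery of the selection rule itself
is therefore measured on a single-contrast configuration.

All randomness flows from one `numpy` generator seeded by
`SimConfig.seed`; identical configs give byte-identical outputs.

### What the generator does not emulate

Probe-sequence affinity (GC or otherwise — GC content can be emitted
but carries no signal), cross-hybridisation, spatial chip artifacts,
position-dependent RNA degradation, and correlated biological
variation between conditions.  Passing tests therefore demonstrate
that the pipeline recovers planted location shifts under idealised
additive background and log-normal noise — not that it would rank
real transcripts correctly in the presence of probe effects the
preprocessing cannot see.

## Preprocessing

The chain is the RMA family: background correction → quantile
normalization → log₂ → median polish.

* **normexp background** (default): observed intensity is modelled as
  normal background plus exponential signal.  Parameters are fitted
  per sample by maximum likelihood (Nelder–Mead on (μ, log σ, log α),
  likelihood evaluated on at most 20,000 evenly spaced order
  statistics for speed; moment-based estimation is unusable here
  because the heavy-tailed signal inflates the third moment by orders
  of magnitude).  Corrected values are the closed-form posterior mean
  `E[S|X=x] = a + σ φ(a/σ)/Φ(a/σ)`, `a = x − μ − σ²/α` — strictly
  positive and monotone.
* **Damping offset**: a constant (default 50 in the full chain, 0 in
  the bare `background_correct`) added after correction.  Log-ratios
  of near-background intensities are otherwise dominated by division
  noise; in replicate-rich designs this is tamed by variance
  moderation, which a replicate-free design does not have, so the
  damping is carried entirely by the offset.  16–50 is the customary
  range; we sit at the damping end.
* **shift-log / gc-stratified**: subtract half the per-sample (or
  per-GC-quintile) column minimum.  Half the minimum is
  scale-equivariant, so multiplying all raw intensities by a constant
  shifts every log₂ expression by exactly the log of that constant.
* **Quantile normalization**: columns are sorted, the per-rank mean
  across chips becomes the reference, values map back by rank; tied
  values receive the mean of the reference values across their tied
  ranks.  After normalization the sorted columns are identical.
* **Median polish** (per probe set, probes × samples, on log₂):
  row sweep before column sweep, effect medians swept into the grand
  effect, `max_iter = 10`, tolerance 0.01 log₂ units, even-length
  medians as the midpoint of the middle pair.  The probe-set
  expression for a sample is grand + sample effect.  Blocks of equal
  size are polished as one vectorised 3-D stack.
* **NUSE**: per (probe set, sample), the MAD-based residual scale
  over that set's probes divided by √(probes per set); normalized by
  the probe set's median SE across samples.  Chips with median NUSE
  well above 1 are imprecise.  Zero residual scale (exactly additive
  set) and single-sample fits report 1 by convention.
* **Degradation profile**: least-squares slope of mean log₂ raw
  intensity against probe position per sample; undefined slopes (one
  position) are flagged rather than silently zero.

## Hexagonal-bin selection

Pointy-top regular hexagons on the (A, M) plane after mapping the
data extents to the unit square (so hexagon regularity does not
depend on the data units); `gridsize` (default 50) hexagons span the
A extent.  The lattice is two offset rectangular grids; a point
belongs to the hexagon with the nearest center, exact ties to the
lexicographically smaller (row, col).  Assignment is verified against
a brute-force nearest-center search in the tests.

Selection ranks hexagons by ascending occupancy and accumulates whole
occupancy tiers (all hexagons sharing a count) until at least
`target_n` probes (default 500) are gathered; the final tier is
ranked by descending |M| (ties: probeset id) and truncated to exactly
`target_n`.  Selected probes are labelled up (M > 0), down (M < 0) or
unchanged (M = 0; excluded from the percentage split).  Consequences:

* the output size is exactly `target_n` whenever at least that many
  points exist, regardless of the magnitude of M — rescaling M by any
  positive constant changes nothing;
* bin membership is invariant under any affine map of either axis
  (extents recomputed); the *selected set* is additionally invariant
  only under sign-preserving scalings, because the final-tier ranking
  uses |M|.  A rule invariant under M-offsets as well would have to
  drop the |M| ranking; the fixed-size property was judged the more
  important contract.
* small-|M| probes at extreme A are legitimately selected — sparse
  regions are sparse regardless of M, which matches how a
  density-based rule behaves on real chips.

## Concordance

Strict-sign classification with M = 0 excluded (`unclassified`); no
magnitude threshold, because the underlying gene sets are reported by
direction only and every published table value is nonzero.  Default
granularity is the probe set; `collapse_to_gene` (largest |M| in the
first contrast) is opt-in.  The four classes partition the input, and
negating all M swaps the two concordant classes while fixing
discordant — both are property-tested.

## qPCR and GO summaries

* ΔΔCt: technical replicates are averaged within group before ΔCt;
  `fold = 2^(−ΔΔCt)` with no amplification-efficiency correction.
* Student's t: pooled equal-variance form (not Welch) with
  `n₁ + n₂ − 2` df.  Zero pooled variance returns t = 0, p = 1 for
  equal means and a flagged infinite t, p = 0 otherwise.
* Category percentages: per GO sub-tree, `percent = round(100 ×
  category_count / total_assignments)`, ties rounding half up, where
  the denominator counts every gene–category assignment in the
  sub-tree (a gene in k categories contributes k).  This convention
  uniquely reproduces every percentage of the packaged 11-gene
  example (denominators 28, 21 and 29 for the three sub-trees).
  Percentages therefore sum to 100 within rounding slack.

## Pipeline

`run_pipeline` chains the stages, writes every artifact as UTF-8 TSV
or JSON, and emits a manifest with SHA-256 checksums; identical
configs produce byte-identical trees.  The per-contrast summary table
(total selected, %up, %down) mirrors the shape of a published DEG
summary; its *numbers* are properties of the synthetic chips — the
original raw chips are not deposited, so no numeric reproduction of
the published per-contrast DEG counts is possible or attempted.

## Problem sizes

Unit tests run on chips of a few hundred probe sets.  The selection
and recovery checks run at the full design size (42,800 probe sets ×
11 probes × 6 samples) in a single-contrast configuration, which
completes in seconds; the recovery check (≥80 % of ~257 planted
probe sets inside the top-500 selection) is evaluated at seed 0 and
typically lands near 85–93 % across seeds.

## Known limitations

* The normexp model is deliberately mis-specified relative to the
  generator's exponential background; the MLE compensates in location
  but residual background survives subtraction and attenuates fold
  changes of weakly expressed transcripts by a few tenths of a log₂
  unit.
* Planted shifts share one magnitude, so they form two bands in the
  MA plane whose hexagons are not maximally sparse; recovery is
  bounded by competition with the natural fringe of the cloud.
* NUSE is computed from a plain median polish, not from the iterated
  reweighting of a full probe-level model fit, so its absolute scale
  is conventional; only deviations from 1 are meaningful.
* The GO stage is percentage arithmetic over user-supplied category
  maps; it performs no annotation, graph propagation or enrichment
  testing.
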