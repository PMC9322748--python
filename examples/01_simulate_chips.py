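"""Generate a synthetic six-chip experiment with planted signal.

Emulates probe-level intensities for a canine expression chip: each
probe set has several probes, every sample is a single unreplicated
chip, and a small fraction of probe sets receives a planted 2.0 log2
shift in the treated member of each contrast.
"""

from mahex import SimConfig, generate_chips

config = SimConfig(n_probesets=2_000, probes_per_set=11, de_fraction=0.01,
                   seed=7)
probes, truth = generate_chips(config)

samples = [c for c in probes.columns if c.startswith("Sample-")]
print(f"probe rows: {len(probes)} ({config.n_probesets} probe sets "
      f"x {config.probes_per_set} probes), samples: {len(samples)}")
print(f"intensity range: {probes[samples].min().min():.1f} .. "
      f"{probes[samples].max().max():.0f}")

per_contrast = truth[truth.true_direction != "null"].groupby("contrast_id").size()
print("planted differential probe sets per contrast:")
print(per_contrast.to_string())
# Each contrast plants ~n_probesets * de_fraction probe sets, split
# evenly between up- and downregulation in the treated sample.
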