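"""Poisson rate coding and integrate-and-fire dynamics.

Scales one synthetic activation epoch to [-1, 1], unrolls it into a ternary
spike train over T = 16 timesteps, and pushes the spikes through the IF
temporal convolution.  The empirical firing rate approximates the scaled
amplitude; the membrane potential after the last timestep is what the deeper
analog blocks consume.
"""

import numpy as np

import spikealpha as sa
from spikealpha.ifneuron import IFState, if_conv_forward

params = sa.SimParams(seed=3)
rng = np.random.default_rng(3)
_, act = sa.gen_trial(sa.OpennessLevel.HIGH, sa.Task.SYMBOLIC, params, rng)

scaled = sa.scale_input(act)
train = sa.poisson_encode(scaled, T=16, rng=rng)
rate = train.firing_rate()
print(f"scaled range: [{scaled.min():.2f}, {scaled.max():.2f}]")
print(f"spike train: shape {train.values.shape}, values {sorted(set(train.values.ravel().tolist()))}")
print(f"mean |rate| = {rate.mean():.3f} vs mean |scaled| = {np.abs(scaled).mean():.3f}")
# rate -> |scaled| as T grows (law of large numbers); at T=16 it is coarse

weights = np.random.default_rng(0).normal(scale=0.2, size=(8, 64))
res = if_conv_forward(train, weights, IFState(v_th=2.0, T=16))
print(f"membrane potential V[T]: shape {res.V.shape}, "
      f"range [{res.V.min():.2f}, {res.V.max():.2f}]")
print(f"threshold crossings: {int(res.output_spikes.sum())} spikes across "
      f"{res.output_spikes.size} units")
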