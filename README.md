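# btspmap

Behavioral-timescale synaptic plasticity (BTSP) as a one-dimensional weight
map: palimpsest memory traces in recurrent networks and their retrieval as
bump attractors.

## The problem

Hippocampal place fields can appear after a single traversal of a novel
track: a dendritic plateau potential (PP) in a CA1 cell potentiates CA3
inputs that were active within a seconds-wide window around the plateau.
Mechanistic models of this process track an eligibility trace per synapse
and a global instructive signal, integrated in continuous time over a lap.
This package implements the reduction of that process to a **one-shot map**
on bounded weights: for a presynaptic place field at phase θ on a circular
track and a plateau at phase θ̄,

    w ← w + P (1 − w) f_P(θ − θ̄) − D w f_D(θ − θ̄),      w ∈ [0, 1],

with spatial plasticity kernels f_P, f_D obtained by converting temporal
skew-t kernels to track coordinates and wrapping them around the circle.

Applied to the recurrent collaterals of a CA3-like network, with one PP per
active cell per environment and global remapping (an independent random
permutation of place-field phases, each cell active with probability s),
the map turns the weight matrix into a palimpsest.  For the symmetric rule
f_P = 1 + cos θ, f_D = 1 − cos θ the trace of the environment explored η
environments ago has closed form:

* mean ordered profile  μ_w + a_η cos Δθ with
  a_η = (2PD/(P+D)) (1 − s²(P+D))^η,
* quenched variability  V_η(Δθ) = A_η + B_η cos Δθ + C_η cos²Δθ
  (explicit recursions in `btspmap.theory`),
* SNR_η = √(sM) a_η / √(A_η + C_η/2) for M cells per phase slot, whose
  threshold crossing gives the structural capacity
  η_max ≈ (1/4s²P) ln(8P(1−P) sM).

The dynamics layer loads the learned matrix into a rate network
τṙᵢ = −rᵢ + φ((1/κN) Σⱼ w̄ᵢⱼ rⱼ Sⱼ + I₀) Sᵢ and asks which past environments
support a persistent activity bump.  Under sparse coding this network is
equivalent to a hierarchy of ring models W(Δθ) = W₀ + W₁^η cos Δθ + noise,
with a Turing bifurcation at W₁ = 2/φ₀′ that quenched variability shifts to
lower W₁ (older memories) by the expected first-mode modulation ⟨R⟩.

## Worked example

```python
import numpy as np
import btspmap as bm

params = bm.MapParams.cosine(P=0.3, D=0.3)
seq = bm.generate_environment_sequence(N=64, M=8, s=0.5, n=80, seed=0)
W0 = np.random.default_rng(1).random((seq.n_cells, seq.n_cells))
W, _ = bm.recurrent_learn(W0, seq, params)

mu, var = bm.steady_state_moments(params)
print(f"grand mean weight     : {W[~np.eye(512, dtype=bool)].mean():.4f}  (theory {mu})")
theory = bm.memory_trace(np.arange(4), 0.3, 0.3, 0.5)
for eta in range(4):
    st = bm.empirical_trace_stats(W, seq, eta)
    print(f"trace amplitude age {eta} : {st.amplitude:.4f}  (theory {theory.a[eta]:.4f})")
cap = bm.snr_capacity(s=0.5, M=8, P=0.3)
print(f"SNR capacity          : {cap.eta_max} environments (closed form {cap.eta_max_closed:.1f})")

wbar = bm.build_effective_weights(W, mu, W_max=40.0, W0=-0.25)
cfg = bm.RateNetConfig(kappa=seq.s * seq.M, W_max=40.0, W0=-0.25)
ok, ro = bm.retrieve(wbar, seq, eta=0, config=cfg, rng=np.random.default_rng(2))
print(f"recall of last track  : retrieved={ok}, bump amplitude "
      f"{ro.amplitudes[seq.env_for_age(0)]:.2f} (null {ro.null_amplitude:.2f})")
```

prints

```
grand mean weight     : 0.4986  (theory 0.5)
trace amplitude age 0 : 0.2999  (theory 0.3000)
trace amplitude age 1 : 0.2472  (theory 0.2550)
trace amplitude age 2 : 0.2149  (theory 0.2167)
trace amplitude age 3 : 0.1797  (theory 0.1842)
SNR capacity          : 6 environments (closed form 6.2)
recall of last track  : retrieved=True, bump amplitude 7.58 (null 0.79)
```

The learned matrix sits at the predicted statistical steady state (mean
1/2 for P = D), the ordered correlation with each past environment decays
geometrically by 1 − s²(P+D) = 0.85 per environment, and seeding the rate
network with a bump in the most recent ordering retrieves it: the
steady-state amplitude is ~10× the shuffled-ordering null and supra-
threshold in exactly that one environment.

The `btsp` command line drives seeded end-to-end experiments:

```sh
btsp presets list
btsp run --preset recurrent_learning --seed 1 --out results/rl
btsp summarize results/rl
```

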