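# nmrdecomp

Signal deconvolution and bidirectional property↔spectrum prediction for
multi-component solid-state NMR.

Broad, overlapping ssNMR spectra of multi-phase materials (polymers,
degrading biomass, whole cells) hide components that differ in molecular
mobility. Each component's free-induction decay dies away with its own
effective transverse relaxation time T2\*: rigid phases decay fast (broad
lines), mobile phases slowly (narrow lines). `nmrdecomp` exploits this by

1. **STFT** — converting an FID s(t) into a short-time Fourier transform
   magnitude matrix V(t, f), whose frame axis samples the T2\* decay of
   every line;
2. **Non-negative factorization** — separating V (one sample, NMF:
   V ≈ Σ_c w_c(t) h_c(f)) or the sample × time × frequency tensor X of a
   measurement series (NTD: X ≈ G ×₁ A ×₂ B ×₃ C with a non-negative core
   G; NCPD: X ≈ Σ_c a_c ∘ b_c ∘ c_c) into per-component spectra, decay
   patterns and sample compositions, by Frobenius-loss multiplicative
   updates;
3. **GTM regression** — fitting a generative topographic map jointly on
   autoscaled descriptor and property blocks \[X | Y\] so that conditioning
   the node responsibilities on either block predicts the other: forward
   (spectrum → property) and inverse (target property → predicted
   spectrum); plus **GMM pseudodata** to feed the regression when no new
   experiments are available.

Because real multi-sample ssNMR series of this kind are rarely deposited,
the package ships a first-class synthetic module that generates
ground-truth fixtures — sums of exponentially decaying complex sinusoids
(Lorentzian lines), a 16-timepoint degradation series over 0–120 h with
smoothly varying component amplitudes, and property tables functionally
linked to composition — so every claim is testable end to end.

## Worked example

Separate a simulated cellulose-degradation series (16 ¹³C CP-MAS-like
samples, three components plus noise) and predict catabolic products:

```python
import numpy as np
from nmrdecomp import (
    align_components, compute_stft, fit_gtmr, make_degradation_series,
    make_fid, ntd, predict_forward, r_squared, stack_tensor,
)
from nmrdecomp.factorize import fit_decay_constant
from nmrdecomp.synthetic import make_product_table

fids, truth = make_degradation_series()
spectrograms = [compute_stft(f, segment_length=128, hop=32) for f in fids]
tensor = stack_tensor(spectrograms, list(truth["composition"].index))
result = ntd(tensor, ranks=(4, 4, 4), tol=1e-3, seed=0)
print(f"NTD rel_error = {result.rel_error:.4f} after {result.n_iter} iterations")

refs = np.array([
    compute_stft(make_fid(lines, 2048, 5e-5), 128, 32).magnitude.sum(axis=0)
    for lines in truth["components"].values()
])
perm, sims = align_components(result, refs)
T = result.spectral_time_profiles()
for ci, name in enumerate(truth["components"]):
    t2 = fit_decay_constant(T[int(perm[ci])], tensor.frame_times)
    print(f"{name:10s} cosine={sims[ci]:.3f}  T2* = {1e3*t2:.1f} ms")

tab = make_product_table(truth["times_h"])
X = tab.column("propionate")[:, None]
Y = np.column_stack([tab.column("acetate"), tab.column("co2")])
model = fit_gtmr(X, Y)
pred = predict_forward(model, X)
print(f"acetate R2 = {r_squared(Y[:, 0], pred.mean[:, 0]):.3f}")
print(f"CO2     R2 = {r_squared(Y[:, 1], pred.mean[:, 1]):.3f}")
```

Output:

```
NTD rel_error = 0.0227 after 590 iterations
cellulose  cosine=0.992  T2* = 4.9 ms
protein    cosine=0.997  T2* = 15.3 ms
lipid      cosine=1.000  T2* = 51.4 ms
acetate R2 = 1.000
CO2     R2 = 1.000
```

The factorization reproduces each component's spectrum (cosine similarity
against the noiseless ground truth ≥ 0.99), its composition time course,
and the mobility ordering — the fast-decaying cellulose-like component has
the shortest T2\*, the mobile lipid-like component the longest. The GTM
regression recovers the acetate- and CO₂-analogue intensities from the
propionate-analogue alone.

The same pipeline is available from the shell:

```sh
nmrdecomp simulate --scenario default --out data/
nmrdecomp deconvolve --method ntd --ranks 4,4,4 --in data/ --out results/ \
    --segment-length 128 --hop 32
cat results/summary.json
```

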