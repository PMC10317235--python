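# beeal — gain control and concentration invariance in the honey-bee antennal lobe

`beeal` is a research package for studying how GABAergic lateral
inhibition shapes odor representations in the insect antennal lobe
(AL).  It bundles two things that are usually kept apart:

1. **A conductance-based network model of the AL** — 20 glomeruli of
   3 uniglomerular projection neurons (PNs) and 5 inhibitory local
   neurons (iLNs) each, 160 two-compartment Hodgkin–Huxley cells wired
   only by GABA-A and GABA-B synapses, with random Bernoulli(0.25)
   iLN→glomerulus connectivity.  Pharmacological blockade (picrotoxin,
   CGP54626) is modeled by zeroing the corresponding conductances.
2. **The calcium-imaging analysis pipeline** used on ratiometric
   Delta(340/380) recordings — logistic concentration-response fits
   with dynamic range DR = EC90 − EC10 = 2 ln 9 / b and sensibility
   Sens = 0.8 a / DR, glomerular recruitment counting against a 2×SD
   baseline criterion, cross-concentration Pearson/Fisher-z pattern
   correlations, blocker-difference traces with time-to-peak
   extraction, and a greedy similarity index that scores model output
   against a reference imaging pattern.

A synthetic-data generator (`beeal.synth`) produces imaging-like
datasets with known ground truth — sigmoid per-glomerulus tuning, a
fast (≈375 ms) and a slow (≈1375 ms) suppression component, and
pattern-stabilising lateral inhibition — so the entire pipeline is
testable without animal recordings.  Who this is for: computational
neuroscientists reproducing or extending AL gain-control models, and
imaging labs wanting a tested, scriptable implementation of these
analyses.

## Worked example

```python
import numpy as np
from beeal import (LayoutSpec, build_topology, topology_stats,
                   GeneratorSpec, generate_imaging_dataset, normalize,
                   fit_gain_curve)
from beeal.imaging import ONSET_FRAME

c = build_topology(LayoutSpec(seed=0))
s = topology_stats(c)
print(f"neurons: {c.neuron_count}, edges: {len(c.edges)}")
print(f"glomeruli inhibited per iLN: {s.mean_glomeruli_per_iln:.2f}")
print(f"iLNs inhibiting each glomerulus: {s.mean_incoming_ilns_per_glomerulus:.2f}")
print(f"unconnected glomerulus pairs: {s.frac_unconnected_ordered_pairs:.3f}")

ds = generate_imaging_dataset(GeneratorSpec(n_bees=4, condition="cocktail", seed=1))
tab = normalize(ds.table, mode="per_bee_saline_max")
frame = ONSET_FRAME + 3          # 375 ms after odor onset
for series, label in ((1, "saline"), (2, "cocktail")):
    sub = tab[(tab.series == series) & tab.log10_conc.notna()
              & (tab.frame == frame)]
    curve = sub.groupby("log10_conc")["value"].mean()
    fit = fit_gain_curve(curve.index.to_numpy(), curve.to_numpy())
    print(f"{label:9s} {fit.summary()}")
```

prints

```
neurons: 160, edges: 3948
glomeruli inhibited per iLN: 5.08
iLNs inhibiting each glomerulus: 25.40
unconnected glomerulus pairs: 0.224
saline    GainFit: a=0.2312  b=2.612  c=-8.849  DR=1.682  Sens=0.1099  resid=0.0118
cocktail  GainFit: a=2.39  b=0.8937  c=-2.16  DR=4.917  Sens=0.3888  resid=0.0728
```

The wiring statistics of this one random network sit near their
ensemble means (5 glomeruli inhibited per iLN, 25 iLNs per glomerulus,
(1−0.25)⁵ ≈ 0.237 of ordered glomerulus pairs unconnected).  The two
logistic fits show the blocker phenotype: removing GABAergic inhibition
multiplies the fitted amplitude — and with it the sensibility, the
slope-like measure 0.8 a / DR — several-fold at the 375 ms analysis
window.

Model-side experiments run the same way:

```python
from beeal import gain_curve
curves = gain_curve(i0_grid=(0, 20, 40, 60, 80, 100),
                    recruit_fraction=0.55, scales=(1.0, 0.5, 0.0),
                    topology_seeds=(3,))
```

returns a tidy table of mean recruited-glomerulus calcium at the
375 ms window; the response-vs-input slope grows as the inhibition
scale drops — gain modulation by lateral inhibition.

A CLI wraps the same functions for shell use:

```sh
beeal topology --out net.json
beeal simulate --out run/ --i0 40 --recruit-fraction 0.55 --quick
beeal synth --out data/ --condition cocktail
beeal analyze gain --in data/ --window 375 --out results/
```

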