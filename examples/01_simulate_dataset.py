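"""Simulate a labelled tipping-point dataset and look at its composition.

Builds a small white-noise dataset from the bifurcation model library: each
series is a length-400 recording of a stochastic model whose control
parameter either ramps through a bifurcation (fold -> catastrophic C.T.;
transcritical/pitchfork/Hopf -> smooth S.T.) or stays sub-critical (N.T.).
Transition series are truncated just before the bifurcation is crossed, so a
classifier only ever sees pre-transition data.
"""

from collections import Counter

import numpy as np

from tippingews import build_dataset

ds = build_dataset("W", n_per_class=10, seed=0)

print(f"{len(ds.series)} series, variant {ds.variant}; "
      f"{len(ds.train)} train / {len(ds.test)} test")
print("class counts:", dict(Counter(s.label for s in ds.series)))
print()
print(f"{'model':24s} {'label':6s} {'length':>6s} {'first':>8s} {'last':>8s}")
for s in ds.series[:8]:
    print(f"{s.model_name:24s} {s.label:6s} {len(s):6d} "
          f"{s.values[0]:8.2f} {s.values[-1]:8.2f}")

# Transition series end where the forcing crosses the bifurcation point
# (length < 400); no-transition series run the full 400 recorded points.
lengths = {lbl: np.mean([len(s) for s in ds.series if s.label == lbl])
           for lbl in ("C.T.", "S.T.", "N.T.")}
print("\nmean length per class:", {k: round(v, 1) for k, v in lengths.items()})
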