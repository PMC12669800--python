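"""Estimate binding affinity from pocket-ligand interface graphs.

Each toy complex carries a planted p-affinity that is linear in its
contact count plus noise. The affinity head is trained on the
heterogeneous residue-atom interface graphs and predictions are printed
against the planted values (p-affinity = -log10 of a molar Kd).
"""

import numpy as np

from dtbind import ModelConfig, make_toy_complex
from dtbind.training import featurize_toy_complex, train_task

config = ModelConfig(h1=32, h2=8, h3=32, h4=32, h5=32, h6=32, dropout=0.0)
complexes = [make_toy_complex(seed) for seed in range(8)]
samples = [featurize_toy_complex(cx, config, with_hetero=True)
           for cx in complexes]

result = train_task("affinity", samples, config, seed=0, epochs=150)
print("train metrics:", {k: round(v, 3)
                         for k, v in result.train_metrics.values.items()})
print("\npair  contacts  planted  predicted")
for cx, s in zip(complexes, samples):
    print(f"{cx.seed:4d}  {cx.contact_count:8d}  {cx.affinity:7.3f}  "
          f"{result.model.predict(s):9.3f}")
print("\nPredictions should track the planted p-affinities, which rise by "
      "0.3 per contact residue from a baseline of 4.0.")
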