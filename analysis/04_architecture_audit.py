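"""Audit the two classifier architectures against their reference totals.

Builds the pinned CNN-dense and CNN-LSTM models, breaks the trainable
parameters down layer by layer, and checks that the totals round to the
reference 2.03e6 and 5.55e5.

Run:  python analysis/04_architecture_audit.py
"""

from pathlib import Path

import pandas as pd

from pcgband import models as m

rows = []
for build, reference in ((m.build_cnn_dense, 2.03e6), (m.build_cnn_lstm, 5.55e5)):
    model = build()
    for i, layer in enumerate(model.net.layers):
        if layer.n_params():
            rows.append({"model": model.tag, "layer": f"{i:02d}_{type(layer).__name__}",
                         "params": layer.n_params()})
    rows.append({"model": model.tag, "layer": "TOTAL", "params": model.n_params})
    rounded = float(f"{model.n_params:.2e}")
    status = "matches" if rounded == reference else "DOES NOT MATCH"
    print(f"{model.tag}: {model.n_params:,} parameters -> {rounded:.3g} "
          f"({status} the reference {reference:.3g})")

frame = pd.DataFrame(rows)
Path("results").mkdir(exist_ok=True)
frame.to_csv("results/04_parameter_counts.csv", index=False)
print("\n" + frame.to_string(index=False))
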