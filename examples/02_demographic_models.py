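"""The seven gene-flow models and their priors.

Prints each model's free parameters and migration structure, draws from the
priors, and shows the epoch behaviour of the glacial-window model G: no
migration during the current interglacial (the most recent 20,000
generations), gene flow during the preceding glacial period, nothing after
the sister taxa merge.
"""

import numpy as np

from coalabc import active_migration_rates, default_priors, draw_parameters, get_model
from coalabc.demographic_models import DEMES, MODEL_CODES

priors = default_priors("nuclear")
print("model catalog (nuclear track):")
for code in MODEL_CODES:
    m = get_model(code)
    edges = ", ".join(
        f"{DEMES[e.deme_i][:4]}<->{DEMES[e.deme_j][:4]}({e.rate_param})"
        for e in m.edges
    ) or "none"
    print(f"  {code}: {m.n_parameters} free parameters; migration: {edges}")

rng = np.random.default_rng(7)
params = draw_parameters(get_model("G"), priors, rng)
print("\none prior draw for model G:")
for k, v in params.items():
    print(f"  {k:14s} {v:12.5g}")
print("(constraints hold: T_cp < T_a and m_ca < m_cp)")

print("\nmodel G migration matrix [chilensis, pallatangae, albiceps]:")
for t, label in [(1e4, "t=10,000 (interglacial: isolated)"),
                 (1e5, "t=100,000 (glacial: gene flow)"),
                 (params["T_cp"] * 1.01, "t just past T_cp (sisters merged)")]:
    print(f"  {label}:")
    print(np.array2string(active_migration_rates(get_model('G'), params, t),
                          prefix="  ", precision=2))
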