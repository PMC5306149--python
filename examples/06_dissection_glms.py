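"""The side-validation GLMs: dissection pairs and host abundance.

Does a 24-hour mesh-bag embryo release reliably indicate embryos in the
mussel gill? Simulated (released, dissected) pairs follow the printed
dissection-model coefficients; fitting recovers them, and the generalised
R^2 contrast (presence predictable, count not) motivates analysing releases
as binary data.
"""

import numpy as np
import pandas as pd

import seasongamm as sg

pairs = sg.generate_dissection_pairs(n=5000, seed=3)
data = pd.DataFrame({
    "released": [p.released for p in pairs],
    "released_any": [p.released_any for p in pairs],
    "dissected": [p.dissected for p in pairs],
})

bern = sg.fit_glm(data, "released_any", ["dissected"], family="bernoulli")
pois = sg.fit_glm(data, "released", ["dissected"], family="poisson")
print("Bernoulli presence model (truth -2.38 + 0.26 x):")
print(bern.summary().round(3).to_string(index=False))
print(f"  generalised R^2 = {sg.generalized_r2(bern):.2f}")
print(f"Poisson count model generalised R^2 = {sg.generalized_r2(pois):.2f}")
print("  -> presence is the reliable signal; counts are not\n")

pi0 = sg.predict_glm((-2.38, 0.26), [0, 5, 15], "bernoulli")
print("release probability at 0/5/15 dissected embryos:", np.round(pi0, 3))

# host-abundance stability: binomial GLMs per species across lake-years
rng = np.random.default_rng(1)
rows = []
for lake in (2, 6, 8, 13):
    for year in (1995, 1996, 1997):
        total = int(rng.integers(90, 150))
        for s, p in zip(sg.SPECIES, (0.40, 0.25, 0.20, 0.15)):
            rows.append({"lake": lake, "year": year, "species": s,
                         "number": int(rng.binomial(total, p)), "total": total})
fits = sg.fit_abundance_models(pd.DataFrame(rows))
from seasongamm.glms import abundance_table
print(abundance_table(fits).round(3).to_string(index=False))
# Near-zero lake-by-year slopes: the host community is stable across years,
# so seasonal infection changes are not an artefact of shifting availability.
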