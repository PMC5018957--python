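"""Bayesian admixture across K = 1..4 with Evanno delta-K model choice.

Two diverged groups are planted, so delta-K peaks at K = 2 and the
posterior-mean ancestry matrix Q assigns each pure accession almost
entirely to one cluster (cluster labels are arbitrary between runs).
Run lengths here are desk-scale; raise burnin/reps for real data.
"""

import numpy as np

import popkit as pk
from popkit.core import BiallelicMatrix

model = pk.PopulationModel(
    chromosome_lengths=(200_000,),
    n_sites=200,
    groups=(pk.GroupSpec("a", 8, 0.3), pk.GroupSpec("b", 8, 0.3)),
    admixed=(("mix_1", {"a": 0.5, "b": 0.5}),),
    seed=21,
)
truth = pk.simulate_populations(model)
matrix = BiallelicMatrix(truth.accessions, truth.sites, truth.genotypes)

fits = pk.fit_k_range(matrix, range(1, 5), n_runs=3, burnin=500, reps=2000, seed=22)
delta = pk.evanno_delta_k({K: [f.log_likelihood for f in fs] for K, fs in fits.items()})
print(delta.to_string(index=False))
print(f"\nbest K by delta-K: {pk.best_k(delta)} (two ancestral populations were planted)")

fit = fits[2][0]
print("\nposterior-mean ancestry (Q) at K = 2:")
for name, q in zip(fit.accessions, np.round(fit.Q, 3)):
    print(f"  {name:8s} {q}")
print(
    "\nmix_1 was planted as a 50/50 blend: unlike the pure accessions its "
    "ancestry is\nsplit across both clusters (at 200 sites the split is "
    "recovered only roughly)."
)
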