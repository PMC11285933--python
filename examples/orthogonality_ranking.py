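"""Rank the 1-chamber model's parameters by orthogonality.

A small sensitivity run (Sobol' design, N = 512, Jansen estimator, discrete
measurements) produces the 3 x 9 total-order matrix; each parameter's
sensitivity column then yields pairwise sine-of-angle orthogonality scores.
Rank 1 marks the parameter whose effect direction is most distinct from the
rest — the best candidate for unique recovery — and the identifiability
index I = E * d combines that with the effect magnitude.
"""

import numpy as np

from cvgsa import (RunConfig, identifiability_index, mean_orthogonality,
                   orthogonality_matrix, rank_by_orthogonality, run_gsa)

res = run_gsa(RunConfig("one_chamber", "sobol", "jansen", N=512,
                        measurements="discrete", seed=1))
S = res.sensitivity_matrix
om = orthogonality_matrix(S, res.indices.parameter_names)
rv = rank_by_orthogonality(om)
effect = np.linalg.norm(S, axis=0)
ident = identifiability_index(effect, mean_orthogonality(om))

print(f"{res.n_evaluations} model evaluations, N = {res.config.N}")
print(f"{'parameter':>10} {'rank':>4} {'mean d':>7} {'effect':>7} {'I':>7}")
order = np.argsort(rv.ranks)
for i in order:
    name = rv.parameter_names[i]
    print(f"{name:>10} {rv.ranks[i]:>4d} {rv.scores[i]:>7.3f}"
          f" {effect[i]:>7.3f} {ident[i]:>7.3f}")
print("\nrank 1 = most orthogonal; high I = influential AND orthogonal,"
      "\nso most likely to be uniquely recoverable from these measurements")
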