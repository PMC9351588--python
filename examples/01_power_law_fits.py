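"""Fit the niche-vs-habitat power law for every taxon of a small community.

Generates a 23-sample x 17-taxon synthetic table (the dimensions of a
phylum-level gut survey), fits y = alpha * H**beta per taxon against the
habitat index H (each sample's total abundance), and prints the fitted
scaling parameters.  beta > 0 means the taxon expands more than
proportionally as the habitat fills up; beta < 0 means it is squeezed out.
"""

import qdnet

matrix, truth = qdnet.generate(qdnet.scenario("phylum17", seed=1))
fits = qdnet.fit_all(matrix)

print(f"{'taxon':>6} {'alpha':>8} {'beta':>7} {'R2(log)':>8}   true beta")
for j, taxon in enumerate(matrix.taxon_ids[:8]):
    f = fits[taxon]
    print(f"{taxon:>6} {f.alpha:8.3f} {f.beta:7.3f} {f.r2_log:8.3f}   {truth.beta[j]:7.3f}")
print("...")
print("The fitted beta tracks the planted exponent; R2(log) is the fit "
      "quality on the log-log scale the regression runs on.")
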