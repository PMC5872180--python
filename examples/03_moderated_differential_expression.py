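"""Moderated-t differential expression on a simulated two-group dataset.

Simulates a 500-gene case/control dataset whose per-gene variances follow the
scaled inverse-chi-square prior (d0 = 4, s0² = 0.05) with 25 genes carrying a
planted ±1.5 log2-fold-change effect, then runs the empirical-Bayes moderated
t with BH FDR control and reports how many planted genes are recovered.
"""

import numpy as np

from netbiomark import run_de
from netbiomark.simulate import make_expression_truth, simulate_expression

rng = np.random.default_rng(2)
genes = [f"g{i:03d}" for i in range(500)]
planted = {g: float(s) * 1.5 for g, s in zip(genes[:25], rng.choice([-1, 1], 25))}

truth = make_expression_truth(
    genes, de_genes=planted, d0=4.0, s0_sq=0.05,
    n_control=10, n_case=10, n_datasets=1, seed=2,
)
dataset = simulate_expression(truth)[0]

table = run_de(dataset, alpha=0.05, method="moderated")
prior = table.attrs["prior"]
print(f"estimated variance prior: d0 = {prior.d0:.2f}, s0^2 = {prior.s0_sq:.4f}")

called = table[table["direction"] != "NS"]
hits = [g for g in planted if g in called.index]
print(f"{len(called)} genes called at FDR < 0.05; {len(hits)}/25 planted recovered")

top = called.reindex(called["p_adj"].sort_values().index).head(5)
print(top[["log_fc", "t_mod", "p_adj", "direction"]].round(4))
# The estimated prior should sit near the generating (4, 0.05); with effects
# of 1.5 log2 units against sd ~ 0.22, essentially all planted genes are
# recovered and direction calls match the planted signs.
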