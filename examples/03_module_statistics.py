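"""Compare a module's wiring between two conditions.

Simulates the differential-module situation: 20 genes nearly uncorrelated in
condition A (rho = 0.05) but tightly correlated in condition B (rho = 0.8).
After network construction, the module statistics table reports per-network
average degree d-bar, density D = d-bar/(n-1), and the Bernoulli
edge-probability t-test p-value: a small p flags a module wired differently
in the two conditions.
"""
from comodule import (
    ModuleSet,
    build_networks,
    differential_expression_scenario,
    generate_correlated_expression,
    stats_table,
)

scenario = differential_expression_scenario(seed=3)
expr_a, expr_b, truth = generate_correlated_expression(scenario)
net_a, net_b, _ = build_networks(expr_a, expr_b, q=0.98)

planted = [g for g, l in zip(truth.gene_ids, truth.labels) if l == 1]
background_sample = [g for g, l in zip(truth.gene_ids, truth.labels) if l == 0][:20]
modules = ModuleSet(gene_ids=truth.gene_ids, modules=[planted, background_sample])

print("module  size  d_A    d_B    D_A    D_B    p-value")
for rec in stats_table(modules, net_a, net_b):
    print(
        f"{rec.module_id:>6}  {rec.size:>4}  {rec.avg_degree_a:<5.2f}  "
        f"{rec.avg_degree_b:<5.2f}  {rec.density_a:<5.2f}  {rec.density_b:<5.2f}  "
        f"{rec.p_value:.2e}"
    )
print("module 1 is the planted differential module (dense only in B);")
print("module 2 is a background control (sparse in both conditions, p not significant)")
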