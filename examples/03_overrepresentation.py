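"""Hypergeometric overrepresentation of a cluster against annotation terms.

Builds an annotation collection with one term per planted module plus
random decoys, then asks which terms are overrepresented in one module.
Strength is log10(observed/expected); FDR is Benjamini-Hochberg.
"""

from mitonet import enrich, simulate_annotations

modules = [
    [f"A{i}" for i in range(8)],
    [f"B{i}" for i in range(8)],
    [f"C{i}" for i in range(6)],
]
universe = {m for module in modules for m in module} | {f"X{i}" for i in range(40)}
annotations = simulate_annotations(modules, n_decoy_terms=10, seed=3, universe=sorted(universe))

result = enrich(set(modules[0]), annotations, universe)
print(f"{'term':<10}{'k':>3}{'K':>4}{'strength':>10}{'p':>12}{'FDR':>12}")
for row in result[:5]:
    print(
        f"{row.term_id:<10}{row.k:>3}{row.K:>4}"
        f"{row.strength:>10.2f}{row.p_value:>12.3g}{row.fdr:>12.3g}"
    )
print()
print(
    "The planted term CL01 contains exactly the queried module, so it tops\n"
    "the table with the smallest achievable p for this configuration, while\n"
    "decoy terms stay near p = 1."
)
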