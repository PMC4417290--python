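"""Panel reduction by greedy backward elimination.

Starts from a 10-gene synthetic panel in which only 4 genes carry the
class difference, and removes genes one at a time while cohort accuracy
does not drop. The trace shows which gene left at each step and the
accuracy after the removal; the final panel is the smallest one found at
the best accuracy on this cohort (resubstitution — see docs/methods.md for
the overfitting caveat).
"""

from her2sig import (
    GeneratorConfig,
    backward_eliminate,
    make_cohort,
    make_references,
)
from her2sig.simulate import informative_genes

cfg = GeneratorConfig(seed=7, n_tumors=40, pcr_fraction=0.5, panel_size=10,
                      n_informative=4, archetype_separation=2.0, noise_sd=1.0)
refs = make_references(cfg)
profiles, labels = make_cohort(cfg)

trace = backward_eliminate(refs.panel, profiles, labels, refs)
print(f"start: {len(refs.panel)} genes, accuracy {trace.start_accuracy:.3f}")
for i, (gene, size, acc) in enumerate(trace.steps, start=1):
    print(f"step {i}: removed {gene:5s} -> {size} genes, accuracy {acc:.3f}")
print(f"final panel: {', '.join(trace.final_panel.genes)} "
      f"(accuracy {trace.final_accuracy:.3f})")
print(f"truly informative genes: {', '.join(informative_genes(cfg))}")
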