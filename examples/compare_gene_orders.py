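"""Compare chilopod gene orders against the ancestral arthropod arrangement.

Loads the packaged orders, prints breakpoint distances and the
rearranged-unit decomposition for the two informative comparisons: the
extensively rearranged *M. marmoratus* against the ancestral order, and
*S. mutilans* against its congener *S. subspinipes*.
"""

from mitorearrange import (
    breakpoint_distance,
    decompose_blocks,
    linear_diagram,
    load_reference_orders,
    polarity_clusters,
)

refs = load_reference_orders()
ancestral = refs["L_polyphemus"]

print("Ancestral arthropod order (minority-strand genes marked '-'):")
print(" ", linear_diagram(ancestral), "\n")

for query_id, ref_id in [("S_subspinipes", "L_polyphemus"),
                         ("M_marmoratus", "L_polyphemus"),
                         ("S_mutilans", "S_subspinipes")]:
    query, reference = refs[query_id], refs[ref_id]
    bp = breakpoint_distance(query, reference)
    print(f"{query_id} vs {ref_id}: breakpoint distance {bp}")
    if bp:
        d = decompose_blocks(query, reference)
        print(f"  {d.rearranged_count} rearranged unit(s): "
              + ", ".join(d.unit_labels))
    print()

# Transcriptional polarity: in M. marmoratus, same-strand genes cluster
# together except one merge-breaking singleton.
report = polarity_clusters(refs["M_marmoratus"])
print("M. marmoratus polarity runs (strand, size):",
      [(s, len(genes)) for s, genes in report.runs])
print("merge-breaking singleton(s):", report.singletons)
# A breakpoint distance of 0 means 'identical up to rotation/reflection';
# each rearranged unit is a maximal block that moved and/or inverted.
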