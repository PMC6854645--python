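"""Date a gene duplication from gene-tree topology.

Two planted scenarios: a duplication before the guayule/sunflower split
(each guayule paralog immediately sister to a sunflower gene) and one in
the guayule lineage itself (the paralogs are mutual sisters). The
classifier reads the rooted tree and reports the event class per paralog.
"""

from droughtleaf.duplication_timing import classify_duplication, root_on_outgroup
from droughtleaf.io_formats import read_newick
from droughtleaf.synthetic_data import SPECIES_MAP, SimulationParams, gen_gene_family

for event in ("asteraceae", "lineage"):
    fam = gen_gene_family(event, SimulationParams(seed=3))
    rooted = root_on_outgroup(fam.tree)  # root on the Arabidopsis ortholog
    call = classify_duplication(rooted, fam.query_tips, support_min=70)
    tips = ", ".join(f"{t}={call.assignments[t].value}" for t in sorted(call.assignments))
    print(f"planted {event:11s} -> cluster {call.cluster_class.value:10s} ({tips})")

# A hand-written tree with one poorly supported node: the weak tip drops to
# UNRESOLVED but the cluster is still dated by the well-supported paralog.
tree = read_newick("(((g1,h1)60,(g2,h2)95),at);", {"g": "Parthenium", "h": "Helianthus", "at": "Arabidopsis"})
call = classify_duplication(tree, ["g1", "g2"], support_min=70)
print(f"low-support node    -> cluster {call.cluster_class.value} "
      f"(g1={call.assignments['g1'].value}, g2={call.assignments['g2'].value})")
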