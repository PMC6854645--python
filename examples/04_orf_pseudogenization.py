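"""Detect pseudogenization inside a paralog cluster.

Evolves a coding gene family, plants a premature stop codon in one
guayule copy, trims the alignment to the Arabidopsis reference CDS and
assesses every paralog's ORF integrity. One disrupted copy among intact
ones is the signature of a pseudogenization event.
"""

from droughtleaf.cluster_alignment import trim_to_cds
from droughtleaf.orf_integrity import assess_orf_in_cluster, cluster_pseudogenization
from droughtleaf.synthetic_data import SimulationParams, gen_gene_family

fam = gen_gene_family("asteraceae", SimulationParams(seed=33), pseudogenize="premature_stop")
trimmed = trim_to_cds(fam.alignment, "at1")
print(f"alignment trimmed to reference CDS: {trimmed.n_columns} columns")

assessments = [assess_orf_in_cluster(trimmed, q, "at1") for q in fam.query_tips]
for a in assessments:
    state = "intact" if a.intact else f"disrupted ({a.reason.value})"
    print(f"  {a.transcript_id}: {state}")
print(f"cluster call : {cluster_pseudogenization(assessments).value}")
print(f"planted truth: {sorted(fam.truth.family.pseudogenized)} disrupted")
# PARTIAL = at least one but not all paralogs lost their reading frame.
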