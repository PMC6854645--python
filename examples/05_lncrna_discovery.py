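"""Run the lncRNA filter cascade on a synthetic candidate panel.

The panel mixes true lncRNAs with protein-coding fragments, TE/rRNA
decoys, and transcripts whose sunflower locus overlaps an annotated
gene. The cascade removes each decoy class at its dedicated stage and
classifies the survivors' cross-species conservation.
"""

from collections import Counter

from droughtleaf.lncrna_discovery import RemovalStage, run_cascade
from droughtleaf.synthetic_data import SimulationParams, gen_lncrna_panel

panel = gen_lncrna_panel(SimulationParams(seed=11))
trails = run_cascade(
    panel.guayule,
    panel.protein_hits,
    panel.decoy_hits,
    panel.sunflower_hits,
    panel.lettuce_hits,
    panel.sunflower_annotation,
    panel.sunflower_lnc_annotation,
    panel.lettuce_lnc_annotation,
)

stage_counts = Counter(t.removed_at.value for t in trails.values())
print(f"candidates in: {len(trails)}")
for stage in RemovalStage:
    print(f"  {stage.value:18s}: {stage_counts.get(stage.value, 0)}")

survivors = [t for t in trails.values() if t.removed_at is RemovalStage.SURVIVOR]
cons = Counter(t.conservation.value for t in survivors)
print(f"survivor conservation: {dict(sorted(cons.items()))}")
truth = {i for i, t in panel.truth.lncrna.items() if t.class_label == "lncrna"}
survivor_ids = {t.transcript_id for t in survivors}
print(f"survivors equal planted lncRNA set: {survivor_ids == truth}")
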