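"""Build the canonical multiplexed biochip layout and inspect it.

Ten capture ligands plus an anti-OVA negative control are placed on a
10 x 10 spot grid: capture ligands own vertical runs in alternating
columns, the control fills the interleaved columns.
"""

from evchip import build_layout, default_panel, ligand_rois

layout = build_layout(default_panel(), 10, 10)

print(f"grid:           {layout.n_rows} x {layout.n_cols} = {len(layout.spots)} spots")
print(f"negative ctrl:  {layout.negative_control} on "
      f"{len(ligand_rois(layout, layout.negative_control))} spots")
for ligand in layout.capture_ligands:
    rois = ligand_rois(layout, ligand)
    print(f"  {ligand:<13} {len(rois)} analysis spots (row-major indices {rois})")

# Every spot belongs to exactly one ligand family: 50 control spots plus
# 10 families x 5 spots account for the whole 100-spot chip.
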