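# Default suturing-quality rubric: a 12-item modification of the 15-item
# Zhang corneal wound-closure scale.  Each item is rated on a 5-point Likert
# scale, so the total ranges from 12 to 60.  Relative to the original 15-item
# instrument, "preoperative preparation", "postoperative clean-up" and
# "knot rotation" are dropped.
#
# Item labels below are representative paraphrases (the original wording is
# not redistributable); scoring arithmetic depends only on the item count
# and the scale bounds.
name: modified-zhang-12
scale:
  min: 1
  max: 5
items:
  - needle_holder_use
  - forceps_and_tissue_handling
  - needle_entry_angle
  - suture_depth
  - bite_symmetry_across_wound
  - stitch_placement_and_spacing
  - loop_formation
  - knot_tying_technique
  - knot_security
  - suture_tension
  - economy_and_fluency_of_movement
  - wound_apposition
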