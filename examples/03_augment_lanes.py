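"""Expand training lanes 15x by rotation, magnification and translation.

Shows the cardinality used per training fold (189 originals -> 2835
images) and the parameter log of the first few variants.
"""

import hbscreen as hb

strip, gt = hb.render_strip(hb.StripSpec(seed=0))
lane = hb.crop_and_resize(strip, gt.lane_boxes[0])
lane.label = gt.labels[0]

variants = hb.augment_image(lane, hb.AugmentSpec(seed=9))
print(f"one lane -> {len(variants)} images (original + 14 variants)")
for v in variants[1:6]:
    print("  ", v.meta["augment"])

print("\nper-fold arithmetic: 189 originals ->",
      len(hb.augment_set([lane] * 189, hb.AugmentSpec(seed=9))),
      "training images")
print("(only training images are augmented; validation and test lanes "
      "are never transformed)")
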