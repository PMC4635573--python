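"""Optional skeleton diagnostic: thinning with junction/terminal points.

Not used by the SNPP estimate — it visualizes panicle branch topology.
"""

from spikescan import (
    SyntheticPanicleSpec,
    binarize,
    generate_panicle,
    otsu_threshold,
    skeleton_vertices,
    to_gray,
)

img, truth = generate_panicle(SyntheticPanicleSpec(seed=8, n_branches=6, target_snpp=70))
gray = to_gray(img)
mask = binarize(gray, otsu_threshold(gray))

sv = skeleton_vertices(mask)
print(f"skeleton pixels:  {int(sv.skeleton.sum())}")
print(f"junctions:        {len(sv.junctions)}")
print(f"terminals:        {len(sv.terminals)}")

print(f"(generated with {len(truth.branches)} branches)")

# Junctions mark branch attachment points, terminals mark branch tips;
# their counts grow with the number of primary branches.
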