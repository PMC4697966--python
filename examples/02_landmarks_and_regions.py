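"""Construct the landmark system and cancellous regions on a section.

The geometric scheme: line a (humeral long axis, fitted to the distal
shaft), line b (cartilage-end chord, the anatomical neck), line c
(perpendicular to a through the caudal cartilage end), line d (parallel
to a, tangent to the distal-medial periosteal contour), line e
(perpendicular bisector of b, ending at the subchondral plate).  One
third of the medial segment of line c is s1; one third of line e is s2.
These subdivide the section into seven cancellous regions.
"""

from humeromorph import construct_landmarks, fit_long_axis, partition_regions
from humeromorph.synth import SectionSpec, generate_section

spec = SectionSpec(head_radius=10.0, shaft_width=9.0, shaft_offset=4.0,
                   cartilage_thickness=0.8, mm_per_pixel=0.05, tail_mm=10.0, seed=2)
section, annotation, truth = generate_section(spec)

axis = fit_long_axis(section, annotation)
lm = construct_landmarks(section, annotation, axis)
lm.validate()  # perpendicularity / parallelism / subdivision invariants

mm = section.mm_per_pixel
print(f"long axis direction (distal->proximal): "
      f"({axis.direction[0]:+.4f}, {axis.direction[1]:+.4f})")
print(f"s1 = {lm.s1_length * mm:.2f} mm   (1/3 of the medial segment of line c)")
print(f"s2 = {lm.s2_length * mm:.2f} mm   (1/3 of line e)")
print(f"head height = {lm.head_height * mm:.2f} mm")
print(f"|line e| = {lm.e_length * mm:.2f} mm  "
      f"(true plate depth: {truth.landmarks.e_length * mm:.2f} mm)")
print()
regions = partition_regions(section, lm)
print(f"{'region':12s} {'area mm^2':>10s}")
for label, poly in regions.regions.items():
    print(f"{label:12s} {poly.area * mm * mm:10.1f}")
print()
print("h splits exactly into the subchondral band (within s2 of the plate)")
print("and the inner region; sc1/sc2 are s2-wide bands distal of the neck;")
print("m1/m2 are s1-wide medial metaphyseal strips distal of line c.")
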