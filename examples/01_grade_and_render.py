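"""Grade roots by weight and render synthetic specimens.

Builds one synthetic taproot per grade, prints its drawn weight, the grade
the weight maps to under the national standard, and the projected area of
the rendered blob — larger, heavier roots are higher grades.
"""

from notoroot import GRADES, SyntheticImageSpec, assign_grade, generate_root_image

spec = SyntheticImageSpec()
print(f"{'grade':>5} {'weight_g':>9} {'assigned':>9} {'area_px':>9}")
for grade in GRADES:
    img, mask, weight = generate_root_image(spec, grade, seed=7)
    print(f"{grade:>5} {weight:9.2f} {assign_grade(weight):>9} {int(mask.sum()):9d}")
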