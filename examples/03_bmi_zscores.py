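"""BMI z-scores through the LMS transform, and the weight meaning of a
small z-score difference.

The LMS method standardizes BMI against an age- and sex-specific
reference: z = ((X/M)^L - 1)/(L*S).  A z-score contrast can be translated
back into kilograms for a reference child, which is how a regression
coefficient of ~0.06 z becomes "about 0.3 kg".
"""

import walkbmi as w

bmi_ref = w.synthetic_growth_reference("bmi")
stature_ref = w.synthetic_growth_reference("stature")

# a 10-year-old boy, 1.40 m and 35 kg
x = w.bmi(35.0, 1.40)
z = w.lms_z(x, bmi_ref, sex=1, age_months=120)
print(f"BMI = {x:.2f} kg/m^2 -> z = {z:+.3f}")

# round trip through the inverse transform
x_back = w.inverse_lms(z, bmi_ref, sex=1, age_months=120)
print(f"inverse_lms(z) = {x_back:.2f} kg/m^2 (round trip)")

for dz in (0.06, 0.11):
    dw = w.weight_difference_for_delta_z(dz, bmi_ref, stature_ref, sex=1, age_years=11)
    print(f"delta z = {dz:.2f} for the median 11-year-old boy -> {dw:.2f} kg")
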