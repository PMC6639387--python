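"""Evaluate the reference sex-specific final LASSO equations.

Inputs are standardized biomarker/demographic values; sex is 1 for female,
0 for male. At all-zero predictors both equations return the shared
intercept 24.597 MMSE points.
"""

from eegslow import predict_final_equation

print("predicted MMSE at the cohort mean (all standardized predictors 0):")
print(f"  male:   {predict_final_equation(0, 0, 0, 0, 0, sex=0):.3f}")
print(f"  female: {predict_final_equation(0, 0, 0, 0, 0, sex=1):.3f}")

print("\none SD of extra EEG slowing (MDF one SD below the mean):")
for sex, label in ((0, "male"), (1, "female")):
    y = predict_final_equation(-1, 0, 0, 0, 0, sex=sex)
    print(f"  {label:6s}: {y:.3f}")
print("  -> the quadratic MDF term makes slowing costlier than speeding is "
      "beneficial")
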