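"""Audit the BMI-shift assumptions behind the obesity-endpoint scenarios.

Under a normal BMI distribution, a stated (mean-BMI reduction, obesity
endpoint) pair implies a unique distribution SD.  Mutually consistent pairs
imply similar SDs; the audit shows the subsidy/legislation pairs cluster
near 9-10 kg/m^2 while the commuting and workplace pairs do not — which is
why scenario runs consume the published obesity-prevalence endpoints directly
rather than converting BMI shifts.
"""

from t2dmsim.bmi import audit_table

report = audit_table()
print(report[["scenario", "bmi_shift", "prev_from", "prev_to",
              "implied_sd"]].to_string(index=False))
spread = report.set_index("scenario").loc[
    ["subsidy_fv", "ssb_tax", "subsidy_ssb_combined"], "implied_sd"]
print(f"\nsubsidy/legislation cluster: SD {spread.min():.2f}-{spread.max():.2f} kg/m^2"
      " (mutually consistent)")
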