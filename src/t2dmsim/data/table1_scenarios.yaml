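# Intervention scenario library: five intervention approaches against T2DM
# (lifestyle management, active commuting, healthy-diet consumption, subsidy &
# legislation, and two combination packages), with uptake, adherence, linear
# scale-up windows, incidence-rate-ratio effects, obesity-prevalence endpoints
# and (informational) mean-BMI reductions.
scenarios:
  - id: lifestyle_obese
    label: Lifestyle management programmes, obese adults
    uptake: 0.50
    adherence: 0.50
    ramp: [2021, 2025]
    filter: {require_obese: true}
    effects: {irr: 0.70}
  - id: lifestyle_age50
    label: Lifestyle management programmes, adults aged 50+
    uptake: 0.50
    adherence: 0.50
    ramp: [2021, 2025]
    filter: {min_age: 50}
    effects: {irr: 0.70}
  - id: lifestyle_obese_35
    label: Lifestyle management programmes, obese adults aged 35+
    uptake: 0.50
    adherence: 0.50
    ramp: [2021, 2025]
    filter: {require_obese: true, min_age: 35}
    effects: {irr: 0.70}
  - id: public_transport
    label: Active commuting via public transportation
    uptake: 0.40
    adherence: 1.00
    ramp: [2021, 2030]
    effects:
      obesity_prev_target: 0.509
      obesity_scope: total
      normalize_inactivity: true
    bmi_shift_info: 0.51
  - id: cycling_walking
    label: Active commuting via cycling or walking
    uptake: 0.20
    adherence: 1.00
    ramp: [2021, 2030]
    effects:
      irr: 0.76
      obesity_prev_target: 0.504
      obesity_scope: total
    bmi_shift_info: 1.68
  - id: fv_consumption
    label: Increased consumption of fruits and vegetables
    uptake: 0.50
    adherence: 1.00
    ramp: [2021, 2030]
    effects: {irr: 0.93}
  - id: vegetables
    label: Increased consumption of vegetables
    uptake: 0.50
    adherence: 1.00
    ramp: [2021, 2030]
    effects: {irr: 0.90}
  - id: green_leafy
    label: Increased consumption of green leafy vegetables
    uptake: 0.50
    adherence: 1.00
    ramp: [2021, 2030]
    effects: {irr: 0.87}
  - id: workplace_diet
    label: Workplace dietary modification and education, working ages 20-65
    uptake: 0.50
    adherence: 1.00
    ramp: [2021, 2030]
    filter: {max_age: 65}
    effects:
      irr: 0.93
      obesity_prev_target: 0.348
      obesity_scope: covered
    bmi_shift_info: 2.4
  - id: subsidy_fv
    label: Subsidies on fruits and vegetables
    uptake: 0.20
    adherence: 1.00
    ramp: [2021, 2030]
    effects:
      obesity_prev_target: 0.526
      obesity_scope: total
    bmi_shift_info: 0.16
  - id: ssb_tax
    label: Taxation on sugar-sweetened beverages
    uptake: 0.20
    adherence: 1.00
    ramp: [2021, 2030]
    effects:
      obesity_prev_target: 0.523
      obesity_scope: total
    bmi_shift_info: 0.24
  - id: subsidy_ssb_combined
    label: Subsidies on fruits and vegetables plus SSB taxation
    uptake: 0.20
    adherence: 1.00
    ramp: [2021, 2030]
    effects:
      obesity_prev_target: 0.516
      obesity_scope: total
    bmi_shift_info: 0.40

packages:
  most_optimistic: [lifestyle_obese_35, cycling_walking, workplace_diet, subsidy_ssb_combined]
  least_optimistic: [lifestyle_obese, public_transport, fv_consumption, subsidy_fv]
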