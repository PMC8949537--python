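# Default record-exclusion rules: conventional plausibility screens for
# adult cohort data.  Ranges are configuration, not constants — override
# with a file of the same shape (keys: variable, min, max, action).
- variable: TEI
  min: 500
  max: 6000
  action: exclude_outside_range
- variable: BMI
  min: 14
  max: 60
  action: exclude_outside_range
- variable: age
  min: 18
  max: 100
  action: exclude_outside_range
- variable: supplement_user
  action: exclude_flagged
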