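category,level,count
questionnaires,distributed,380
questionnaires,valid,351
role,older_adult,241
role,caregiver,110
sex,female,207
sex,male,144
age_band,30-60,66
age_band,60-70,197
age_band,70+,88
disease,heart_disease,139
disease,hypertension,101
disease,pneumonia,79
disease,osteoarthritis,32
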