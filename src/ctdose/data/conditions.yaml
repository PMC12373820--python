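# Default 32-item diagnosed-condition checklist ("Have you ever been diagnosed
# with any of the following medical conditions?") and the severe
# neuropsychological disorders used as exclusion criteria. Both lists are
# configurable; this file ships the defaults.
conditions:
  - adhd
  - anxiety
  - depression
  - substance_use_disorder
  - sleep_disorder
  - bipolar_disorder          # exclusion
  - schizophrenia             # exclusion
  - dementia                  # exclusion
  - parkinsons_disease        # exclusion
  - stroke                    # exclusion
  - epilepsy                  # exclusion
  - traumatic_brain_injury    # exclusion
  - multiple_sclerosis        # exclusion
  - ocd
  - ptsd
  - eating_disorder
  - autism_spectrum_disorder
  - learning_disability
  - migraine
  - chronic_pain
  - diabetes
  - hypertension
  - heart_disease
  - asthma
  - copd
  - cancer
  - thyroid_disorder
  - arthritis
  - kidney_disease
  - liver_disease
  - hearing_loss
  - vision_impairment
exclusion_conditions:
  - bipolar_disorder
  - schizophrenia
  - dementia
  - parkinsons_disease
  - stroke
  - epilepsy
  - traumatic_brain_injury
  - multiple_sclerosis
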