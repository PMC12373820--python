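# Published dataset-dependent benchmark values for the real deposited study
# data (OSF https://osf.io/u6dyg/). These are verification targets for runs of
# the pipeline on the REAL data via the adapter's column mapping; they are
# dataset properties and are not expected from (nor compared against)
# synthetic cohorts.
requires_download: true
source: "OSF deposit u6dyg (real-world ADHD-SRLD cognitive-training study)"
targets:
  overall_adhd_plus_n: 19717
  overall_total_n: 143806
  ncpt_efficacy_low_n: 616
  ncpt_efficacy_high_n: 1330
  cronbach_alpha_attention_controls: 0.718
  cronbach_alpha_mood_controls: 0.745
  cronbach_alpha_attention_adhd: 0.701
  cronbach_alpha_mood_adhd: 0.737
  baseline_hedges_g_attention: 0.708
  baseline_hedges_g_mood: 0.330
  baseline_hedges_g_gi: 0.198
  dose_hedges_g_gi: 0.440
  dose_hedges_g_attention: 0.524
  responder_odds_gi_high: 0.773
  responder_odds_gi_low: 0.342
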