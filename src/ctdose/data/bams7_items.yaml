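# BAMS-7 item map: 7 items, two response sets, two subscales.
# Numeric recoding is 0-4 with 0 always the most negative option; `reverse`
# means the most negative option is the LAST label of the response set.
# Other 7-item scales can be scored by swapping this file.
response_sets:
  frequency:
    - "Never"
    - "1-2 times during the month"
    - "1-2 times per week"
    - "Several times per week"
    - "Almost every day"
  agreement:
    - "Strongly disagree"
    - "Disagree"
    - "Neither agree nor disagree"
    - "Agree"
    - "Strongly agree"
items:
  lost_details:
    prompt: "How often did you lose track of details (past month)?"
    response_set: frequency
    subscale: Attention
    reverse: true            # "Almost every day" is most negative -> 0
  misplaced_items:
    prompt: "How often did you misplace items (past month)?"
    response_set: frequency
    subscale: Attention
    reverse: true
  lost_concentration:
    prompt: "How often did you lose concentration (past month)?"
    response_set: frequency
    subscale: Attention
    reverse: true
  good_concentration:
    prompt: "I had good concentration (past week)."
    response_set: agreement
    subscale: Attention
    reverse: false           # "Strongly agree" is most positive -> 4
  anxious:
    prompt: "I felt anxious (past week)."
    response_set: agreement
    subscale: Mood
    reverse: true            # "Strongly agree" is most negative -> 0
  bad_mood:
    prompt: "I was in a bad mood (past week)."
    response_set: agreement
    subscale: Mood
    reverse: true
  sad:
    prompt: "I felt sad (past week)."
    response_set: agreement
    subscale: Mood
    reverse: true
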