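# Example common-data-elements mapping for the starter protocol
# (surveygraph new <dir>). Element names follow the archive template;
# `sources` feeds the fixed metadata columns from graph variables.
template: anxiety01
activity: screening
sources:
  interview_age: age
items:
  q1: anx_nervous
  q2: anx_worry_control
  q3: anx_worry_much
  q4: anx_relax
  q5: anx_restless
  severity: symptom_severity
  anxiety_score: anx_subscale_mean
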