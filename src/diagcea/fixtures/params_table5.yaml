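ai_npv:
  family: fixed
  params:
  - 0.712054794520548
ai_precision:
  family: fixed
  params:
  - 0.74
c_ai:
  family: fixed
  params:
  - 0.0
  unit: USD
c_ecg:
  family: fixed
  params:
  - 708.0
  unit: USD
c_echo:
  family: fixed
  params:
  - 1852.0
  unit: USD
c_expert:
  family: fixed
  params:
  - 174.28
  unit: USD
prevalence:
  family: fixed
  params:
  - 0.41
se_echo:
  family: fixed
  params:
  - 0.726
shd_predict_rate:
  family: fixed
  params:
  - 0.27
sp_echo:
  family: fixed
  params:
  - 0.807
t_ai:
  family: fixed
  params:
  - 0.0
  unit: weeks
t_ecg:
  family: fixed
  params:
  - 0.0
  unit: weeks
t_echo:
  family: fixed
  params:
  - 2.0
  unit: weeks
t_expert:
  family: fixed
  params:
  - 4.0
  unit: weeks
u_fn:
  family: fixed
  params:
  - -0.25
u_fp:
  family: fixed
  params:
  - 0.75
u_tn:
  family: fixed
  params:
  - 0.95
u_tp:
  family: fixed
  params:
  - 0.85
yd_echo:
  family: fixed
  params:
  - 0.29
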