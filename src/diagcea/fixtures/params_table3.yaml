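ai_branch_rate:
  family: fixed
  params:
  - 1.0
ai_precision:
  family: uniform
  params:
  - 0.1
  - 0.9
c_cma:
  family: lognormal
  params:
  - 6.8628
  - 0.3
  unit: USD
c_es:
  family: gamma
  params:
  - 4.0
  - 1211.8675
  unit: USD
c_expert:
  family: fixed
  params:
  - 174.28
  unit: USD
c_gp:
  family: lognormal
  params:
  - 7.297758908227872
  - 0.4
  unit: USD
prevalence:
  family: fixed
  params:
  - 0.1665
se_cma:
  family: fixed
  params:
  - 0.9068
se_es:
  family: fixed
  params:
  - 0.9593
se_gp:
  family: fixed
  params:
  - 0.896
sp_cma:
  family: fixed
  params:
  - 0.944
sp_es:
  family: fixed
  params:
  - 0.9933
sp_gp:
  family: fixed
  params:
  - 0.925
t_ai:
  family: fixed
  params:
  - 0.0
  unit: weeks
t_cma:
  family: uniform
  params:
  - 1.0
  - 3.0
  unit: weeks
t_es:
  family: uniform
  params:
  - 4.0
  - 12.0
  unit: weeks
t_expert:
  family: fixed
  params:
  - 4.0
  unit: weeks
t_gp:
  family: uniform
  params:
  - 2.0
  - 6.0
  unit: weeks
u_fn:
  family: uniform
  params:
  - -0.5
  - 0.0
u_fp:
  family: uniform
  params:
  - 0.7
  - 0.8
u_tn:
  family: uniform
  params:
  - 0.9
  - 1.0
u_tp:
  family: uniform
  params:
  - 0.8
  - 0.9
yd_cma:
  family: beta
  params:
  - 154.0
  - 1382.0
yd_es_tier1:
  family: beta
  params:
  - 27.0
  - 46.0
yd_es_tier2:
  family: beta
  params:
  - 35.0
  - 65.0
yd_es_tier3:
  family: beta
  params:
  - 228.0
  - 464.0
yd_gp:
  family: beta
  params:
  - 234.0
  - 1871.0
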