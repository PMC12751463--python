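ai_branch_rate:
  family: fixed
  params:
  - 1.0
ai_precision:
  family: fixed
  params:
  - 0.87
c_cma:
  family: fixed
  params:
  - 871.39
  unit: USD
c_es:
  family: fixed
  params:
  - 4847.47
  unit: USD
c_expert:
  family: fixed
  params:
  - 174.28
  unit: USD
c_gp:
  family: fixed
  params:
  - 1600.0
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
  family: fixed
  params:
  - 2.0
  unit: weeks
t_es:
  family: fixed
  params:
  - 8.0
  unit: weeks
t_expert:
  family: fixed
  params:
  - 4.0
  unit: weeks
t_gp:
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
yd_cma:
  family: fixed
  params:
  - 0.10026041666666667
yd_es_tier1:
  family: fixed
  params:
  - 0.3698630136986301
yd_es_tier2:
  family: fixed
  params:
  - 0.35
yd_es_tier3:
  family: fixed
  params:
  - 0.32947976878612717
yd_gp:
  family: fixed
  params:
  - 0.21238938053097345
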