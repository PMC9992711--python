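# Registry of reported macroscopic values the simulator is checked against.
# tolerance types: sem_or_rel -> max(3*sem, rel*|value|); abs -> +/- abs;
# rel -> rel*|value|.
targets:
  t1:
    preset: wt_gtp
    metric: tau1_on
    units: s
    value: 0.22
    sem: 0.02
    tolerance: {type: sem_or_rel, rel: 0.20}
  t2:
    preset: wt_gtp
    metric: tau2_on
    units: s
    value: 1.92
    sem: 0.30
    tolerance: {type: sem_or_rel, rel: 0.20}
  t3:
    preset: wt_gtp
    metric: pct_step1_on
    units: "%"
    value: 50.0
    tolerance: {type: abs, abs: 10.0}
  t4:
    preset: wt_gdpbs
    ref_preset: wt_gtp
    metric: slowdown_ratio
    units: fold
    value: 5.0
    tolerance: {type: rel, rel: 0.30}
  t5:
    preset: rgb_gtp
    metric: tau_on
    units: s
    value: 0.23
    sem: 0.04
    tolerance: {type: sem_or_rel, rel: 0.20}
  t6:
    preset: gab_gtp
    metric: tau_on
    units: s
    value: 1.45
    sem: 0.19
    tolerance: {type: sem_or_rel, rel: 0.20}
  t7:
    preset: gab_gdpbs
    metric: tau_on
    units: s
    value: 10.38
    sem: 1.46
    tolerance: {type: sem_or_rel, rel: 0.20}
  t8:
    preset: rgb_gtp
    metric: tau_off
    units: s
    value: 0.53
    sem: 0.04
    tolerance: {type: sem_or_rel, rel: 0.20}
  t9:
    preset: gab_gtp
    metric: tau_off
    units: s
    value: 21.37
    sem: 1.34
    tolerance: {type: sem_or_rel, rel: 0.20}
  t10:
    preset: wt_gtp
    metric: ec50
    units: uM
    value: 0.112
    tolerance: {type: rel, rel: 0.25}
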