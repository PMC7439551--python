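# ALS-register-like schema: 11 static + 14 dynamic clinical variables.
# Ordinal ALSFRS-R items are scored 0 (worst) to 4 (normal function).
- {name: sex, temporal_kind: static, scale: categorical, levels: [female, male]}
- {name: bmi_premorbid, temporal_kind: static, scale: continuous, units: kg/m^2}
- {name: bmi_diagnosis, temporal_kind: static, scale: continuous, units: kg/m^2}
- {name: fvc_diagnosis, temporal_kind: static, scale: continuous, units: '%'}
- {name: familiality, temporal_kind: static, scale: categorical, levels: ['no', 'yes']}
- {name: genetics, temporal_kind: static, scale: categorical,
   levels: [C9orf72, FUS, SOD1, TARDBP, wild_type]}
- {name: ftd, temporal_kind: static, scale: categorical, levels: ['no', 'yes']}
- {name: onset_site, temporal_kind: static, scale: categorical, levels: [bulbar, limb]}
- {name: age_at_onset, temporal_kind: static, scale: continuous, units: years}
- {name: diagnostic_delay, temporal_kind: static, scale: continuous, units: months}
- {name: onset_delta, temporal_kind: static, scale: continuous, units: months}
- {name: alsfrs_1, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_2, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_3, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_4, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_5, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_6, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_7, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_8, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_9, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_10, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_11, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: alsfrs_12, temporal_kind: dynamic, scale: ordinal, levels: [0, 1, 2, 3, 4]}
- {name: niv, temporal_kind: dynamic, scale: categorical, levels: ['no', 'yes']}
- {name: peg, temporal_kind: dynamic, scale: categorical, levels: ['no', 'yes']}
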