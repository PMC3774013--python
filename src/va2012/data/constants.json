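{
  "n_causes_2007": 106,
  "n_causes_2012": 62,
  "n_indicators_2007": 408,
  "n_indicators_2012": 221,
  "n_retained": 164,
  "n_new": 57,
  "n_excluded": 244,
  "n_subsumed": 27,
  "cod_related_by_group": {
    "adult": {"level_1": 56, "level_2": 37, "level_3": 27, "level_4": 10, "total": 130},
    "child": {"level_1": 34, "level_2": 35, "level_3": 22, "level_4": 10, "total": 101},
    "neonate": {"level_1": 44, "level_2": 35, "level_3": 15, "level_4": 10, "total": 104}
  },
  "distinct_by_level": {"level_1": 93, "level_2": 87, "level_3": 31, "level_4": 10, "total": 221},
  "non_cod_by_group": {"personal": 26, "respondent": 3, "context": 10},
  "group_totals": {"adult": 169, "child": 140, "neonate": 143}
}
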