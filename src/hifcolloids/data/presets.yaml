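# Fed-state duodenal-fluid composition presets (mM), one per healthy
# volunteer (HV), as quantified in pooled aspirates collected within 2 h
# after a meal.  Classes: bile_salt, phospholipid, fatty_acid, cholesterol,
# MAG/DAG/TAG (mono-/di-/tri-acylglycerides).
HV3:
  bile_salt: 10.8
  phospholipid: 4.2
  fatty_acid: 11.1
  cholesterol: 0.5
  MAG: 7.1
  DAG: 1.8
  TAG: 1.1
HV6:
  bile_salt: 28.0
  phospholipid: 6.9
  fatty_acid: 13.8
  cholesterol: 1.0
  MAG: 5.6
  DAG: 1.7
  TAG: 0.5
HV9:
  bile_salt: 13.6
  phospholipid: 6.5
  fatty_acid: 44.9
  cholesterol: 0.3
  MAG: 10.4
  DAG: 2.7
  TAG: 1.3
HV16:
  bile_salt: 10.7
  phospholipid: 7.7
  fatty_acid: 38.4
  cholesterol: 1.7
  MAG: 9.8
  DAG: 1.9
  TAG: 1.5
HV20:
  bile_salt: 15.4
  phospholipid: 4.2
  fatty_acid: 27.2
  cholesterol: 0.5
  MAG: 10.6
  DAG: 4.1
  TAG: 2.2
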