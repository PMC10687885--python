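# Default RUG-III/HC classification rule configuration.
#
# The hierarchical skeleton (7 categories evaluated in priority order, split
# into 23 groups by ADL band / IADL difficulty / service counters) is fixed by
# the RUG-III/HC system. The clinical trigger item lists and the split
# thresholds below are editable data: they are a documented, simplified
# stand-in for the original grouper's item logic, with one flag or score per
# trigger class.
#
# ADL scale: 4 items coded 1 (independent) .. 5 (total dependence), unit
# weights; the summed score (4..20) is banded A (low limitation) through D
# (highest). IADL scale: 3 items coded 0 (no difficulty) .. 3 (dependent);
# "some" difficulty means any item at or above the cut-point.

adl_scale:
  items: [eating, transfer, toilet_use, locomotion]
  code_min: 1
  code_max: 5
  weights: {eating: 1.0, transfer: 1.0, toilet_use: 1.0, locomotion: 1.0}
  band_cutpoints: {A: 7, B: 12, C: 16}   # upper bounds; above C -> D

iadl_scale:
  items: [meal_preparation, housework, finances]
  code_min: 0
  code_max: 3
  difficulty_cutpoint: 1

categories:
  - name: Rehabilitation
    trigger: {therapy_minutes_min: 120.0}
    splits:
      - {adl_bands: [B, C, D], group: RB}
      - {adl_bands: [A], iadl: some, group: RA2}
      - {adl_bands: [A], iadl: none, group: RA1}

  - name: ExtensiveServices
    trigger: {clinical_any: [iv_medication, tracheostomy_care, ventilator]}
    splits:
      - {services_min: 3, group: SE3}
      - {services_min: 2, group: SE2}
      - {services_min: 1, group: SE1}

  - name: SpecialCare
    trigger: {clinical_any: [pressure_ulcer_stage3, feeding_tube, radiation_therapy, quadriplegia]}
    splits:
      - {adl_bands: [B, C, D], group: SSB}
      - {adl_bands: [A], group: SSA}

  - name: ClinicallyComplex
    trigger: {clinical_any: [pneumonia, dehydration, internal_bleeding, chemotherapy, dialysis, oxygen_therapy, wound_care]}
    splits:
      - {adl_bands: [C, D], group: CC}
      - {adl_bands: [B], group: CB}
      - {adl_bands: [A], iadl: some, group: CA2}
      - {adl_bands: [A], iadl: none, group: CA1}

  - name: ImpairedCognition
    trigger: {cognitive_performance_min: 3}
    splits:
      - {adl_bands: [B, C, D], group: IB}
      - {adl_bands: [A], iadl: some, group: IA2}
      - {adl_bands: [A], iadl: none, group: IA1}

  - name: BehaviourProblems
    trigger: {behaviour_any: [wandering, verbally_abusive, physically_abusive, socially_inappropriate, resists_care]}
    splits:
      - {adl_bands: [B, C, D], group: BB}
      - {adl_bands: [A], iadl: some, group: BA2}
      - {adl_bands: [A], iadl: none, group: BA1}

  - name: ReducedPhysicalFunctions
    trigger: {always: true}
    splits:
      - {adl_bands: [D], group: PD}
      - {adl_bands: [C], group: PC}
      - {adl_bands: [B], group: PB}
      - {adl_bands: [A], iadl: some, group: PA2}
      - {adl_bands: [A], iadl: none, group: PA1}
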