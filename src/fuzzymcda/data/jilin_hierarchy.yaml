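# Jilin Province food-safety collaborative-governance indicator system:
# 1 goal, 4 second-level indicators (A1-A4), 18 third-level indicators,
# with the published entropy/AHP weights (third-level weights are global,
# i.e. they sum to ~1 across all 18 leaves; sibling groups are renormalized
# on use).
scale:
  labels: [very unimportant, unimportant, average, important, very important]
  values: [1, 2, 3, 4, 5]
nodes:
  - id: A
    label: The effect of collaborative governance on food safety
    level: 1
  - id: A1
    label: Government regulatory capacity (G)
    level: 2
    parent: A
    weight: 0.3850984
  - id: A2
    label: Implementation of corporate responsibility (E)
    level: 2
    parent: A
    weight: 0.11727
  - id: A3
    label: Third parties and inspection quality (T)
    level: 2
    parent: A
    weight: 0.2438468
  - id: A4
    label: Public participation (C)
    level: 2
    parent: A
    weight: 0.2537846
  - id: G1
    label: Supervise the Gini coefficient/urban-rural ratio of human resources and funds
    level: 3
    parent: A1
    weight: 0.079366
  - id: G2
    label: The coverage and targeting of food safety supervision and sampling inspection
    level: 3
    parent: A1
    weight: 0.031488
  - id: G3
    label: The timeliness of responses to illegal acts and regional differences
    level: 3
    parent: A1
    weight: 0.040207
  - id: G4
    label: The frequency and case type distribution of cross-departmental collaborative law enforcement
    level: 3
    parent: A1
    weight: 0.034251
  - id: G5
    label: The transparency and understandability of regulatory information disclosure
    level: 3
    parent: A1
    weight: 0.199787
  - id: E1
    label: The certification rates of food safety management systems in enterprises of different scales
    level: 3
    parent: A2
    weight: 0.022291
  - id: E2
    label: The enterprise scale gradient of traceability information completeness
    level: 3
    parent: A2
    weight: 0.020426
  - id: E3
    label: The differences in the coverage and effectiveness of training for practitioners
    level: 3
    parent: A2
    weight: 0.024855
  - id: E4
    label: The authenticity of the self-inspection report submission rate and the problem discovery rate
    level: 3
    parent: A2
    weight: 0.025572
  - id: E5
    label: Industry and scale differences in the proportion of food safety investment to revenue
    level: 3
    parent: A2
    weight: 0.024126
  - id: T1
    label: The regional equilibrium index of the distribution of testing institution outlets
    level: 3
    parent: A3
    weight: 0.026714
  - id: T2
    label: The transparency of service charge standards and the affordability of small and micro enterprises
    level: 3
    parent: A3
    weight: 0.104797
  - id: T3
    label: The stability of the timeliness of issuing test reports and the fulfillment rate of commitments
    level: 3
    parent: A3
    weight: 0.051819
  - id: T4
    label: The openness of proficiency testing and flight inspection results and the differences among institutions
    level: 3
    parent: A3
    weight: 0.060518
  - id: C1
    label: Group differences in food safety risk perception and knowledge level
    level: 3
    parent: A4
    weight: 0.063173
  - id: C2
    label: Analysis of the differences in the utilization efficiency of complaint and reporting channels
    level: 3
    parent: A4
    weight: 0.038505
  - id: C3
    label: The representativeness and accessibility of participation in policy consultation and risk communication activities
    level: 3
    parent: A4
    weight: 0.098182
  - id: C4
    label: The deviation in the attention paid to food safety issues by the media and social platforms
    level: 3
    parent: A4
    weight: 0.053924
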