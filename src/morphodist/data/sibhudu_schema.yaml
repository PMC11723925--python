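# Default variable schema for unretouched-flake attribute tables from the
# Sibhudu (KwaZulu-Natal) Middle Stone Age sequence: 16 mixed-scale attributes
# recorded per flake, plus a cultural-phase grouping column.
#
# `reference_counts` are the published whole-assemblage level counts
# (n = 4,512 flakes); they seed the synthetic-assemblage generator's default
# marginal distributions and are not used when analysing real data.
group_column: PHASE
group_levels: ["1", "2", "3", "4"]
variables:
  - name: RMA
    label: Raw material
    scale: nominal
    levels: ["1", "2", "3", "4", "5"]
    level_labels: [Dolerite, Hornfels, Sandstone, Quartzite, Quartz]
    reference_counts: [3189, 263, 638, 250, 172]
    reference_na: 0
  - name: CPE
    label: Percent cortex
    scale: continuous
    reference_na: 2
  - name: LEN
    label: Length
    scale: continuous
    geometry: true
    reference_na: 1358
  - name: WID
    label: Width
    scale: continuous
    geometry: true
    reference_na: 837
  - name: THI
    label: Thickness
    scale: continuous
    geometry: true
    reference_na: 42
  - name: EPA
    label: Exterior platform angle
    scale: continuous
    reference_na: 305
  - name: SHA
    label: Shape
    scale: nominal
    levels: ["1", "2", "3", "4", "5"]
    level_labels: [Convergent, Divergent, Round/oval, Parallel/sub-parallel, Rectangular]
    reference_counts: [725, 675, 331, 742, 922]
    reference_na: 1117
  - name: BUL
    label: Bulb
    scale: ordinal
    levels: ["1", "2", "3", "4", "5"]
    level_labels: [Absent, Poor-developed, Developed, Shattered, Well-developed]
    reference_counts: [692, 1107, 1200, 996, 476]
    reference_na: 41
  - name: ESC
    label: Eraillure scar
    scale: nominal
    levels: ["0", "1"]
    level_labels: [Absent, Present]
    reference_counts: [4353, 159]
    reference_na: 0
  - name: LIP
    label: Lip
    scale: nominal
    levels: ["0", "1"]
    level_labels: [Absent, Present]
    reference_counts: [4149, 363]
    reference_na: 0
  - name: HCO
    label: Hertzian cone
    scale: nominal
    levels: ["0", "1"]
    level_labels: [Absent, Present]
    reference_counts: [4386, 126]
    reference_na: 0
  - name: PTY
    label: Platform type
    scale: nominal
    levels: ["1", "2", "3", "4", "5", "6"]
    level_labels: [Cortical, Plain, Facetted, Dihedral, Crushed/shattered, Linear/punctiform]
    reference_counts: [302, 2958, 505, 364, 251, 85]
    reference_na: 47
  - name: PWI
    label: Platform width
    scale: continuous
    geometry: true
    reference_na: 490
  - name: PTH
    label: Platform thickness
    scale: continuous
    geometry: true
    reference_na: 142
  - name: NNU
    label: Number of negatives
    scale: ordinal
    levels: ["0", "1", "2", "3", "4", "5", "6", "7", "8", "9"]
    reference_counts: [75, 487, 1256, 1500, 804, 289, 70, 18, 3, 1]
    reference_na: 9
  - name: NOR
    label: Orientation of negatives
    scale: nominal
    levels: ["1", "2", "3", "4", "5"]
    level_labels: [Parallel, Opposed, Convergent, Orthogonal, Centripetal]
    reference_counts: [1281, 504, 153, 1024, 820]
    reference_na: 730
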