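# Default pelvimetry measure definitions: 15 measures (13 lengths, 2 angles)
# computed from the canonical 12-landmark roster (10 bilateral + 2 midline).
# Lengths in mm, angles in degrees.  Endpoint specs are either a landmark
# {landmark: name, side: left|right|midline} or the midpoint of two
# landmarks {midpoint: [spec, spec]}.
version: 1
measures:
  - name: obstetric_conjugate
    kind: distance
    endpoints:
      - {landmark: promontory}
      - midpoint:
          - {landmark: pubic_symphysis_superior, side: left}
          - {landmark: pubic_symphysis_superior, side: right}
  - name: diagonal_conjugate
    kind: distance
    endpoints:
      - {landmark: promontory}
      - midpoint:
          - {landmark: pubic_symphysis_inferior, side: left}
          - {landmark: pubic_symphysis_inferior, side: right}
  - name: transverse_diameter_inlet
    kind: distance
    endpoints:
      - {landmark: iliopectineal_eminence, side: left}
      - {landmark: iliopectineal_eminence, side: right}
  - name: interspinous_diameter
    kind: distance
    endpoints:
      - {landmark: ischial_spine, side: left}
      - {landmark: ischial_spine, side: right}
  - name: intertuberous_diameter
    kind: distance
    endpoints:
      - {landmark: ischial_tuberosity, side: left}
      - {landmark: ischial_tuberosity, side: right}
  - name: anteroposterior_outlet
    kind: distance
    endpoints:
      - {landmark: lower_sacrum_border}
      - midpoint:
          - {landmark: pubic_symphysis_inferior, side: left}
          - {landmark: pubic_symphysis_inferior, side: right}
  - name: intercrestal_diameter
    kind: distance
    endpoints:
      - {landmark: iliac_crest, side: left}
      - {landmark: iliac_crest, side: right}
  - name: inter_antero_superior_iliac_spine
    kind: distance
    endpoints:
      - {landmark: antero_superior_iliac_spine, side: left}
      - {landmark: antero_superior_iliac_spine, side: right}
  - name: inter_postero_superior_iliac_spine
    kind: distance
    endpoints:
      - {landmark: postero_superior_iliac_spine, side: left}
      - {landmark: postero_superior_iliac_spine, side: right}
  - name: sacral_length
    kind: distance
    endpoints:
      - {landmark: promontory}
      - {landmark: lower_sacrum_border}
  - name: pubic_symphysis_height
    kind: distance
    endpoints:
      - midpoint:
          - {landmark: pubic_symphysis_superior, side: left}
          - {landmark: pubic_symphysis_superior, side: right}
      - midpoint:
          - {landmark: pubic_symphysis_inferior, side: left}
          - {landmark: pubic_symphysis_inferior, side: right}
  - name: left_oblique_diameter
    kind: distance
    endpoints:
      - {landmark: iliopectineal_eminence, side: left}
      - {landmark: postero_superior_iliac_spine, side: right}
  - name: right_oblique_diameter
    kind: distance
    endpoints:
      - {landmark: iliopectineal_eminence, side: right}
      - {landmark: postero_superior_iliac_spine, side: left}
  - name: subpubic_angle
    kind: angle
    apex:
      midpoint:
        - {landmark: pubic_symphysis_inferior, side: left}
        - {landmark: pubic_symphysis_inferior, side: right}
    rays:
      - {landmark: ischium_inferior_ramus, side: left}
      - {landmark: ischium_inferior_ramus, side: right}
  - name: pectineal_angle
    kind: angle
    lines:
      - - {landmark: pubic_tubercle, side: left}
        - {landmark: iliopectineal_eminence, side: left}
      - - {landmark: pubic_tubercle, side: right}
        - {landmark: iliopectineal_eminence, side: right}
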