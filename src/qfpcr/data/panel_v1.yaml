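# Default one-tube QF-PCR marker panel ("panel_v1").
# 20 markers targeting 26 genomic positions: 3 STRs for chromosome 13,
# 4 for 18, 4 for 21, six sex-chromosome markers and three AZFc markers.
# Heterozygosity values are population estimates; only D18S390/D18S391
# are authoritative, the rest are placeholders pending panel revalidation.
version: panel_v1
markers:
  - name: D13S258
    dye: FAM
    marker_class: STR
    role: autosome_dosage
    targets: ["13"]
    position: 13q21.33
    size_range: [238.0, 278.0]
    repeat_unit: 2
    heterozygosity: 0.80
  - name: D13S305
    dye: VIC
    marker_class: STR
    role: autosome_dosage
    targets: ["13"]
    position: 13q13.3
    size_range: [420.0, 460.0]
    repeat_unit: 4
    heterozygosity: 0.78
  - name: D13S1817
    dye: NED
    marker_class: STR
    role: autosome_dosage
    targets: ["13"]
    position: 13q12.11
    size_range: [185.0, 225.0]
    repeat_unit: 4
    heterozygosity: 0.75
  - name: D18S390
    dye: FAM
    marker_class: STR
    role: autosome_dosage
    targets: ["18"]
    position: 18q22.2
    size_range: [380.0, 420.0]
    repeat_unit: 4
    heterozygosity: 0.681
  - name: D18S391
    dye: VIC
    marker_class: STR
    role: autosome_dosage
    targets: ["18"]
    position: 18p11.31
    size_range: [140.0, 176.0]
    repeat_unit: 4
    heterozygosity: 0.685
  - name: D18S386
    dye: NED
    marker_class: STR
    role: autosome_dosage
    targets: ["18"]
    position: 18q22.1
    size_range: [334.0, 382.0]
    repeat_unit: 4
    heterozygosity: 0.88
  - name: D18S535
    dye: PET
    marker_class: STR
    role: autosome_dosage
    targets: ["18"]
    position: 18q12.3
    size_range: [455.0, 500.0]
    repeat_unit: 4
    heterozygosity: 0.82
  - name: D21S11
    dye: FAM
    marker_class: STR
    role: autosome_dosage
    targets: ["21"]
    position: 21q21.1
    size_range: [218.0, 266.0]
    repeat_unit: 4
    heterozygosity: 0.85
  - name: D21S1411
    dye: VIC
    marker_class: STR
    role: autosome_dosage
    targets: ["21"]
    position: 21q22.3
    size_range: [260.0, 308.0]
    repeat_unit: 4
    heterozygosity: 0.89
  - name: D21S1435
    dye: NED
    marker_class: STR
    role: autosome_dosage
    targets: ["21"]
    position: 21q21.3
    size_range: [152.0, 188.0]
    repeat_unit: 4
    heterozygosity: 0.76
  - name: D21S1270
    dye: PET
    marker_class: STR
    role: autosome_dosage
    targets: ["21"]
    position: 21q22.11
    size_range: [290.0, 330.0]
    repeat_unit: 4
    heterozygosity: 0.83
  - name: DXS6803
    dye: FAM
    marker_class: STR
    role: x_count
    targets: ["X"]
    position: Xq21.31
    size_range: [100.0, 112.0]
    repeat_unit: 4
    heterozygosity: 0.74
  - name: XHPRT
    dye: PET
    marker_class: STR
    role: x_count
    targets: ["X"]
    position: Xq26.2
    size_range: [262.0, 298.0]
    repeat_unit: 4
    heterozygosity: 0.77
  - name: DXYS218
    dye: NED
    marker_class: STR
    role: xy_count
    targets: ["X", "Y"]
    position: Xp22.33/Yp11.32 (PAR1)
    size_range: [232.0, 268.0]
    repeat_unit: 2
    heterozygosity: 0.81
  - name: AMELX/Y
    dye: VIC
    marker_class: fixed_size
    role: xy_count
    targets: ["X", "Y"]
    position: Xp22.2/Yp11.2
    products:
      - {chrom: "X", size: 104.0}
      - {chrom: "Y", size: 110.0}
  - name: TAF9B
    dye: PET
    marker_class: fixed_size
    role: x_vs_autosome_count
    targets: ["X", "3"]
    position: Xq13.1/3p24.2
    products:
      - {chrom: "X", size: 141.0}
      - {chrom: "3", size: 145.0}
  - name: SRY
    dye: FAM
    marker_class: fixed_size
    role: y_presence
    targets: ["Y"]
    position: Yp11.2
    products:
      - {chrom: "Y", size: 463.0}
  - name: MYPT2/Y
    dye: VIC
    marker_class: fixed_size
    role: azfc
    targets: ["1", "Y"]
    position: 1q32.1/Yq11.223
    products:
      - {chrom: "1", size: 197.0}
      - {chrom: "Y", size: 205.0}
  - name: DYS448
    dye: NED
    marker_class: STR
    role: azfc
    targets: ["Y"]
    position: Yq11.223
    size_range: [283.0, 313.0]
    repeat_unit: 6
  - name: CDY1/2
    dye: FAM
    marker_class: fixed_size
    role: azfc
    targets: ["Y", "Y", "Y"]
    position: Yq11.223 (CDY1a/CDY1b)/Yp11.2 (CDY2)
    products:
      - {chrom: "Y", size: 334.0}
      - {chrom: "Y", size: 339.0}
      - {chrom: "Y", size: 344.0}
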