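# Default methanogenesis marker-set configuration.
#
# A pathway is an ordered list of required steps; a step is present in a
# MAG if ANY of its `any_of` marker groups is fully present (markers
# within a group are ANDed, so multi-subunit complexes count as units).
# Auxiliary modules are satisfied the same way and are reported as
# variant flags, not pathway steps. Marker labels are a controlled
# vocabulary, annotation-tool-agnostic.
version: 1
pathways:
  - name: hydrogenotrophic
    steps:
      - name: fwd
        any_of: [[fwd], [fmd]]
      - name: ftr
        any_of: [[ftr]]
      - name: mch
        any_of: [[mch]]
      - name: mtd
        any_of: [[mtd]]
      - name: mer
        any_of: [[mer]]
      - name: mtr
        any_of: [[mtr]]
      - name: mcr
        any_of: [[mcr]]
  - name: acetoclastic
    steps:
      - name: acetate_activation
        any_of: [[acs], [ackA, pta]]
      - name: cdh
        any_of: [[cdh]]
      - name: mtr
        any_of: [[mtr]]
      - name: mcr
        any_of: [[mcr]]
  - name: methylotrophic
    steps:
      - name: methyltransferase
        any_of: [[mts], [mta], [mtm], [mtb], [mtt]]
      - name: mcr
        any_of: [[mcr]]
modules:
  - name: hdr_mvh
    any_of: [[hdrA, hdrB, hdrC, mvhA, mvhD, mvhG]]
  - name: ech_eha_ehb
    any_of: [[ech], [eha], [ehb]]
  - name: fpo_hdrD
    any_of: [[fpo, hdrD]]
  - name: rhp
    any_of: [[rhp]]
flags:
  - name: h2_dependent_methylotrophic
    requires_complete: methylotrophic
    requires_absent_markers: [mtr]
    requires_module: hdr_mvh
# transporter/osmolyte genes recorded for bookkeeping only
aux_markers:
  - glycine_betaine_transporter
  - osmoprotectant_transporter
  - oligosaccharide_transporter
  - monosaccharide_transporter
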