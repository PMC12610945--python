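name: aging-panel-10
alpha: 0.05
markers:
  - name: gamma_h2ax
    display: "gamma-H2A.X foci"
    readout: foci_count
    channel: gamma_h2ax
    category: primary
    expected_direction: up
    test: anova2_sidak
  - name: h3k9me3
    display: "H3K9Me3 (CTCF)"
    readout: ctcf
    channel: h3k9me3
    category: primary
    expected_direction: down
    test: anova2_sidak
  - name: telomere
    display: "Telomere content (T/S)"
    readout: telomere_tlr
    category: primary
    expected_direction: down
    test: anova2_sidak
  - name: p21
    display: "p21 (CDKN1A) expression"
    readout: qpcr_fold
    category: antagonistic
    expected_direction: up
    test: anova2_sidak
  - name: p16
    display: "p16 (CDKN2A) expression"
    readout: qpcr_fold
    category: antagonistic
    expected_direction: up
    test: anova2_sidak
  - name: sa_bgal
    display: "SA-beta-Gal activity"
    readout: mean_intensity_cell
    channel: sa_bgal
    category: antagonistic
    expected_direction: up
    test: anova2_sidak
  - name: il6
    display: "IL-6 secretion"
    readout: elisa
    category: antagonistic
    expected_direction: up
    test: anova2_sidak
  - name: il8
    display: "IL-8 secretion"
    readout: elisa
    category: antagonistic
    expected_direction: up
    test: anova2_sidak
  - name: lamin_b1
    display: "Lamin B1 (CTCF)"
    readout: ctcf
    channel: lamin_b1
    category: antagonistic
    expected_direction: down
    test: anova2_sidak
  - name: nucleus_area
    display: "Nucleus area (px)"
    readout: nucleus_area
    category: antagonistic
    expected_direction: up
    test: anova2_sidak
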