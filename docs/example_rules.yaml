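# Example annotation rules for `lolscout annotate-sp --rules ...`.
# Values shown are the package defaults. NOTE: les_pattern is a placeholder
# motif used by the synthetic sequence generator; replace it with a curated
# lipoprotein-export-signal consensus when annotating real proteomes.
lipobox_pattern: "[LVIFMSTAG][ASTVIG][GAS]C"
lipobox_search_window: [10, 40]
spi_h_region_min_hydrophobicity: 1.0
spi_h_region_length: 7
spi_cleavage_motif: "A[^PC]A"
les_pattern: "[DE][DE]"
les_window_length: 6
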