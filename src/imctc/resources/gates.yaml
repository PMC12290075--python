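# Leukocyte gating scheme on arcsinh-transformed ion counts (cofactor 1).
# Thresholds are configuration, not constants of the method: asinh(3.6) ~ 2.0
# separates expressed (tens of counts) from background (<1 count) markers in
# the synthetic scenario; adjust per panel/instrument.
cofactor: 1.0
gates:
  - name: leukocyte
    parent: null
    rules: {CD45: ">= 2.0", CK8_18: "< 2.0"}
  - name: T cell
    parent: leukocyte
    rules: {CD3: ">= 2.0"}
  - name: CD4 T cell
    parent: T cell
    rules: {CD4: ">= 2.0", CD8a: "< 2.0"}
  - name: CD8 T cell
    parent: T cell
    rules: {CD8a: ">= 2.0", CD4: "< 2.0"}
  - name: B cell
    parent: leukocyte
    rules: {CD20: ">= 2.0", CD3: "< 2.0"}
  - name: monocyte
    parent: leukocyte
    rules: {CD14: ">= 2.0", CD68: ">= 1.5", CD3: "< 2.0", CD20: "< 2.0"}
  - name: NK cell
    parent: leukocyte
    rules: {CD56: ">= 2.0", CD3: "< 2.0", CD20: "< 2.0", CD14: "< 2.0"}
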