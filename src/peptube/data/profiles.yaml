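# Force-field profile registry.
#
# Canonical profiles name published force fields; their parameter data is
# licensed/published material consumed as user-supplied files, never shipped
# or re-derived here, so they resolve with data_missing until the user
# points them at templates (atomistic) or mapping+parameter tables (coarse).
# The two "fixture" profiles carry this package's own toy data so every
# pipeline stage runs out of the box.
profiles:
  - {name: Amber03,     resolution: atomistic, canonical: true}
  - {name: Amber94,     resolution: atomistic, canonical: true}
  - {name: Amber96,     resolution: atomistic, canonical: true}
  - {name: Amber99,     resolution: atomistic, canonical: true}
  - {name: OPLS-AA,     resolution: atomistic, canonical: true}
  - {name: CHARMM36,    resolution: atomistic, canonical: true}
  - {name: MARTINI2.2,  resolution: coarse,    canonical: true}
  - {name: MARTINI2.2P, resolution: coarse,    canonical: true}
  - {name: MARTINI3.0,  resolution: coarse,    canonical: true}
  - {name: MARSTINI,    resolution: coarse,    canonical: true}
  - name: fixture-cg
    resolution: coarse
    canonical: false
    mapping: bead_mapping.yaml
    params: cg_params.yaml
  - name: fixture-aa
    resolution: atomistic
    canonical: false
    templates:
      GGGG: linear_topologies/gly4_linear.itp
    internal_charges:
      {N: -0.47, H: 0.31, CA: 0.12, HA2: 0.02, HA3: 0.02, C: 0.51, O: -0.51}
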