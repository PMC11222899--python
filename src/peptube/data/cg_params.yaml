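# Toy bonded-parameter table for the "fixture-cg" profile (GROMACS units:
# nm, kJ/mol, degrees).  Keys are looked up most-specific first:
#   "<code>:<bead>-<bead>"  residue-specific side-chain terms
#   "<roles>:<ss>"          backbone terms per secondary-structure class
#   "<roles>"               generic fallback (SC1/SC2 generalise to SC)
# All residues of a flat D,L-ring are assigned the extended/beta class "E".
bonds:
  "BB-BB:E": {b0: 0.350, k: 1250.0}
  "BB-SC": {b0: 0.330, k: 7500.0}
  "SC-SC": {b0: 0.300, k: 5000.0}
angles:
  "BB-BB-BB:E": {theta0: 134.0, k: 25.0}
  "BB-BB-SC": {theta0: 100.0, k: 25.0}
  "BB-SC-SC": {theta0: 150.0, k: 25.0}
  default: {theta0: 120.0, k: 10.0}
dihedrals:
  "BB-BB-BB-BB:E": {phi0: 180.0, k: 10.0, mult: 1}
  default: {phi0: 0.0, k: 1.0, mult: 1}
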