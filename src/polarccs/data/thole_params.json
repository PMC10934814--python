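{
  "_comment": "Default Thole induced-dipole parameters: exponential damping (dimensionless factor 2.1304) with per-element isotropic polarizabilities in cubic angstroms from a standard molecular fit. Na is the closed-shell cation value and P a transferable estimate; override via a user parameter file for other chemistries.",
  "damping_form": "exponential",
  "damping_factor": 2.1304,
  "atomic_polarizabilities": {
    "H": 0.41381,
    "C": 1.28858,
    "N": 0.97156,
    "O": 0.85194,
    "F": 0.44476,
    "P": 1.56000,
    "S": 2.47446,
    "Cl": 2.40028,
    "Br": 3.49290,
    "I": 5.48104,
    "Na": 0.15000
  }
}
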