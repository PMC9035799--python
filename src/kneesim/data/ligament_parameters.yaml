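# Reference strain and stiffness of the 18 ligament bundle classes of the
# cruciate-retaining TKA knee model.  Reference strain is the strain assigned
# at the extended reference (calibration) pose; negative values mean the
# bundle is slack at extension.  Stiffness is in Newton per unit strain.
# linear_limit_strain is the strain at which the toe (quadratic) region of
# the force-strain law hands over to the linear region (the law is quadratic
# on [0, 2*linear_limit_strain]).
#
# The posterior capsule class (PC) expands into four bundles (PC1-PC4)
# sharing this single parameter row.
bundles:
  - {name: aALL,  reference_strain:  0.01, stiffness_N: 2000, linear_limit_strain: 0.03}
  - {name: pALL,  reference_strain:  0.01, stiffness_N: 2000, linear_limit_strain: 0.03}
  - {name: aLCL,  reference_strain:  0.03, stiffness_N: 2500, linear_limit_strain: 0.03}
  - {name: pLCL,  reference_strain:  0.03, stiffness_N: 2500, linear_limit_strain: 0.03}
  - {name: aMCL,  reference_strain:  0.04, stiffness_N: 2750, linear_limit_strain: 0.03}
  - {name: cMCL,  reference_strain:  0.04, stiffness_N: 2750, linear_limit_strain: 0.03}
  - {name: pMCL,  reference_strain:  0.05, stiffness_N: 2750, linear_limit_strain: 0.03}
  - {name: aDM,   reference_strain:  0.01, stiffness_N: 2000, linear_limit_strain: 0.03}
  - {name: pDM,   reference_strain:  0.04, stiffness_N: 4000, linear_limit_strain: 0.03}
  - {name: aPCL,  reference_strain: -0.10, stiffness_N: 9000, linear_limit_strain: 0.03}
  - {name: pPCL,  reference_strain: -0.05, stiffness_N: 9000, linear_limit_strain: 0.03}
  - {name: PC,    reference_strain:  0.07, stiffness_N: 1000, linear_limit_strain: 0.03}
  - {name: sMPFL, reference_strain:  0.07, stiffness_N: 1200, linear_limit_strain: 0.03}
  - {name: cMPFL, reference_strain:  0.07, stiffness_N: 1100, linear_limit_strain: 0.03}
  - {name: iMPFL, reference_strain:  0.07, stiffness_N: 1000, linear_limit_strain: 0.03}
  - {name: sLPFL, reference_strain:  0.06, stiffness_N: 1200, linear_limit_strain: 0.03}
  - {name: cLPFL, reference_strain:  0.06, stiffness_N: 1100, linear_limit_strain: 0.03}
  - {name: iLPFL, reference_strain:  0.06, stiffness_N: 1000, linear_limit_strain: 0.03}
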