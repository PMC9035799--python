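# Synthetic ligament attachment geometry for a generic RIGHT knee, in mm.
#
# Frame convention (both bodies): x anterior (+), y superior (+), z lateral
# (+); medial is negative z.  Origins are in the femoral body frame (origin at
# the knee center on the flexion axis); insertions are in the tibial body
# frame (origin at the knee center on the tibial joint line), except the six
# patellofemoral bundles whose insertions are in a patellar surrogate frame
# held fixed relative to the tibia (the patellofemoral joint is not solved).
#
# These coordinates are a documented synthetic stand-in for subject-specific
# CT-derived geometry: femoral collateral attachments sit on the epicondyles
# at +/-45 mm from the midline near the flexion axis, tibial insertions
# 28-52 mm distal, cruciate and capsule attachments posterior-central.
# Extension lengths fall in the physiologic 25-60 mm range.  All values are
# overridable via a model configuration file.
bundles:
  aMCL:  {side: medial,  origin: [  6.0,   0.0, -45.0], insertion: [  8.0, -52.0, -33.0]}
  cMCL:  {side: medial,  origin: [  0.0,   0.0, -45.0], insertion: [  0.0, -50.0, -33.0]}
  pMCL:  {side: medial,  origin: [ -6.0,   0.0, -45.0], insertion: [ -8.0, -48.0, -33.0]}
  aDM:   {side: medial,  origin: [  4.0,  -4.0, -43.0], insertion: [  4.0, -28.0, -38.0]}
  pDM:   {side: medial,  origin: [ -4.0,  -4.0, -43.0], insertion: [ -4.0, -28.0, -38.0]}
  aLCL:  {side: lateral, origin: [  4.0,   0.0,  45.0], insertion: [  4.0, -38.0,  42.0]}
  pLCL:  {side: lateral, origin: [ -4.0,   0.0,  45.0], insertion: [ -4.0, -38.0,  42.0]}
  aALL:  {side: lateral, origin: [  8.0,  -2.0,  44.0], insertion: [ 16.0, -35.0,  38.0]}
  pALL:  {side: lateral, origin: [  4.0,  -4.0,  44.0], insertion: [ 12.0, -35.0,  40.0]}
  aPCL:  {side: cruciate, origin: [-12.0,   2.0,  -8.0], insertion: [-28.0, -20.0,  -2.0]}
  pPCL:  {side: cruciate, origin: [-16.0,  -2.0,  -4.0], insertion: [-32.0, -22.0,   2.0]}
  PC1:   {side: posterior, origin: [-22.0,  12.0, -27.0], insertion: [-28.0, -18.0, -27.0]}
  PC2:   {side: posterior, origin: [-22.0,  12.0,  -9.0], insertion: [-28.0, -18.0,  -9.0]}
  PC3:   {side: posterior, origin: [-22.0,  12.0,   9.0], insertion: [-28.0, -18.0,   9.0]}
  PC4:   {side: posterior, origin: [-22.0,  12.0,  27.0], insertion: [-28.0, -18.0,  27.0]}
  sMPFL: {side: patellofemoral-medial,  origin: [ 2.0,  8.0, -44.0], insertion: [42.0, 18.0, -18.0]}
  cMPFL: {side: patellofemoral-medial,  origin: [ 2.0,  2.0, -45.0], insertion: [42.0, 12.0, -18.0]}
  iMPFL: {side: patellofemoral-medial,  origin: [ 2.0, -4.0, -44.0], insertion: [42.0,  6.0, -18.0]}
  sLPFL: {side: patellofemoral-lateral, origin: [ 2.0,  8.0,  44.0], insertion: [42.0, 18.0,  18.0]}
  cLPFL: {side: patellofemoral-lateral, origin: [ 2.0,  2.0,  45.0], insertion: [42.0, 12.0,  18.0]}
  iLPFL: {side: patellofemoral-lateral, origin: [ 2.0, -4.0,  44.0], insertion: [42.0,  6.0,  18.0]}
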