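# Directional trend expectations for the implant malposition study.
# Each entry compares a variant outcome profile against the reference over a
# flexion window (degrees) and asserts a direction.  Advisory entries are
# reported but not asserted: they probe geometry-sensitive nuances that a
# synthetic anatomy is not held to.  Windows and minimum effects are in the
# outcome's units (N, mm or deg).
expectations:
  # --- tibial insert thickness (SI translation of the insert) -------------
  - id: thickness_up2_axial_low_flexion
    variant: tibial_translation_SI_+2mm
    outcome: axial_force
    window: [0, 5]
    direction: increase
    min_effect: 50.0
    note: a thicker insert tightens the ligament apparatus and raises the
      contact force near extension
  - id: thickness_up1_axial_low_flexion
    variant: tibial_translation_SI_+1mm
    outcome: axial_force
    window: [0, 5]
    direction: increase
    min_effect: 25.0
  - id: thickness_down1_axial_low_flexion
    variant: tibial_translation_SI_-1mm
    outcome: axial_force
    window: [0, 5]
    direction: decrease
    min_effect: 25.0
  - id: thickness_down2_axial_low_flexion
    variant: tibial_translation_SI_-2mm
    outcome: axial_force
    window: [0, 5]
    direction: decrease
    min_effect: 50.0

  # --- anteroposterior shift of the femoral component ---------------------
  - id: fem_posterior_axial_high_flexion
    variant: femoral_translation_AP_-3mm
    outcome: axial_force
    window: [60, 80]
    direction: increase
    min_effect: 50.0
    note: posterior femoral shift keeps the larger distal radius engaged in
      flexion, separating the components and loading the ligaments
  - id: fem_anterior_axial_high_flexion
    variant: femoral_translation_AP_+3mm
    outcome: axial_force
    window: [60, 80]
    direction: decrease
    min_effect: 50.0
  - id: fem_posterior_pcl_high_flexion
    variant: femoral_translation_AP_-3mm
    outcome: PCL
    window: [60, 80]
    direction: increase
    min_effect: 10.0
    note: PCL tension, engaged at high flexion, rises with a posterior shift
  - id: fem_anterior_pcl_high_flexion
    variant: femoral_translation_AP_+3mm
    outcome: PCL
    window: [60, 80]
    direction: decrease
    min_effect: 10.0
    note: anterior shift slackens the PCL toward zero tension
  - id: fem_anterior_rollback_absent
    variant: femoral_translation_AP_+3mm
    outcome: ap_femur
    window: [60, 80]
    direction: decrease
    min_effect: 0.5
    advisory: true
    patella_on_only: true
    note: with the PCL slack the femur sits overall more posterior at high
      flexion and the rollback inflection disappears; sensitive to the
      quadriceps mechanism, so advisory only

  # --- internal/external twist of the tibial insert -----------------------
  - id: twist_int3_tibial_rotation
    variant: tibial_rotation_long_+3deg
    outcome: ie_tibia
    window: [0, 80]
    direction: opposite-sign
    min_effect: 0.3
    note: the tibia rotates opposite to the insert twist as a new
      equilibrium establishes
  - id: twist_int6_tibial_rotation
    variant: tibial_rotation_long_+6deg
    outcome: ie_tibia
    window: [0, 80]
    direction: opposite-sign
    min_effect: 0.3
  - id: twist_ext3_tibial_rotation
    variant: tibial_rotation_long_-3deg
    outcome: ie_tibia
    window: [0, 80]
    direction: opposite-sign
    min_effect: 0.3
  - id: twist_ext6_tibial_rotation
    variant: tibial_rotation_long_-6deg
    outcome: ie_tibia
    window: [0, 80]
    direction: opposite-sign
    min_effect: 0.3

  # --- mediolateral shift of the femoral component ------------------------
  - id: fem_lat3_ml_follow
    variant: femoral_translation_ML_+3mm
    outcome: ml_tibia
    window: [0, 80]
    direction: same-sign-comparable
    comparable: [0.2, 1.2]
    note: the tibia follows a mediolateral femoral shift in the same
      direction with nearly parallel profiles
  - id: fem_lat6_ml_follow
    variant: femoral_translation_ML_+6mm
    outcome: ml_tibia
    window: [0, 80]
    direction: same-sign-comparable
    comparable: [0.2, 1.2]
  - id: fem_med3_ml_follow
    variant: femoral_translation_ML_-3mm
    outcome: ml_tibia
    window: [0, 80]
    direction: same-sign-comparable
    comparable: [0.2, 1.2]
  - id: fem_med6_ml_follow
    variant: femoral_translation_ML_-6mm
    outcome: ml_tibia
    window: [0, 80]
    direction: same-sign-comparable
    comparable: [0.2, 1.2]
  - id: fem_lat6_mcl_loading
    variant: femoral_translation_ML_+6mm
    outcome: MCL
    window: [0, 30]
    direction: increase
    min_effect: 3.0
    note: lateralising the femoral component loads the medial collateral
      side near extension
  - id: fem_lat3_mcl_loading
    variant: femoral_translation_ML_+3mm
    outcome: MCL
    window: [0, 30]
    direction: increase
    min_effect: 3.0
  - id: fem_med6_lcl_loading
    variant: femoral_translation_ML_-6mm
    outcome: LCL
    window: [0, 30]
    direction: increase
    min_effect: 3.0
    note: medialising the femoral component loads the lateral collateral side
  - id: fem_med3_lcl_loading
    variant: femoral_translation_ML_-3mm
    outcome: LCL
    window: [0, 30]
    direction: increase
    min_effect: 3.0
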