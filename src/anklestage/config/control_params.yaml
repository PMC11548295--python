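# Virtual-scene control parameters per Brunnstrom stage.
#
# lambda_* are the per-axis response coefficients mapping real ankle
# rotation to virtual-scene motion sensitivity (dimensionless gains,
# non-decreasing with recovery), and max_contact_distance is the obstacle
# contact distance in scene length units (strictly decreasing with
# recovery: more recovered patients get harder collision tolerances).
stages:
  I:   {lambda_x: 0.6, lambda_y: 0.6, lambda_z: 0.6, max_contact_distance: 5.0}
  II:  {lambda_x: 0.8, lambda_y: 0.8, lambda_z: 0.8, max_contact_distance: 4.0}
  III: {lambda_x: 1.0, lambda_y: 1.0, lambda_z: 1.0, max_contact_distance: 3.0}
  IV:  {lambda_x: 1.2, lambda_y: 1.2, lambda_z: 1.2, max_contact_distance: 2.0}
  V:   {lambda_x: 1.4, lambda_y: 1.4, lambda_z: 1.4, max_contact_distance: 1.0}
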