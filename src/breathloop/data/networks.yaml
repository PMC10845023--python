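# Cortical region seeds (head frame, meters: +x right, +y anterior, +z up)
# and their assignment to the three cognitive networks analyzed:
#   DMN  - default mode network (medial prefrontal, posterior
#          cingulate/precuneus, bilateral angular gyri)
#   FPN  - fronto-parietal network (bilateral dorsolateral prefrontal,
#          bilateral superior parietal)
#   CON  - cingulo-opercular network (bilateral anterior insula, dorsal
#          anterior cingulate)
# Sources within `roi_radius_m` of a seed belong to that region; all other
# cortical patches are unassigned background ("none").
roi_radius_m: 0.016
regions:
  mpfc:            {xyz: [0.000,  0.058,  0.038], network: DMN}
  pcc_precuneus:   {xyz: [0.000, -0.048,  0.052], network: DMN}
  angular_l:       {xyz: [-0.050, -0.058,  0.035], network: DMN}
  angular_r:       {xyz: [0.050, -0.058,  0.035], network: DMN}
  dlpfc_l:         {xyz: [-0.042,  0.048,  0.042], network: FPN}
  dlpfc_r:         {xyz: [0.042,  0.048,  0.042], network: FPN}
  sup_parietal_l:  {xyz: [-0.032, -0.030,  0.062], network: FPN}
  sup_parietal_r:  {xyz: [0.032, -0.030,  0.062], network: FPN}
  ant_insula_l:    {xyz: [-0.058,  0.020,  0.010], network: CON}
  ant_insula_r:    {xyz: [0.058,  0.020,  0.010], network: CON}
  dacc:            {xyz: [0.000,  0.028,  0.058], network: CON}
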