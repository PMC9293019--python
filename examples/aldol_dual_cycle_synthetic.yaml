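reaction_type: aldol
temperature: 298.15
points:
- name: INT1a_distal
  role: intermediate
  cycle: A
  conformer: distal
  g_rel: 0.4
- name: INT1a_proximal
  role: intermediate
  cycle: A
  conformer: proximal
  g_rel: 0.0
- name: INT1b_distal
  role: intermediate
  cycle: B
  conformer: distal
  g_rel: -0.5
- name: INT1b_proximal
  role: intermediate
  cycle: B
  conformer: proximal
  g_rel: 0.3
- name: RC1a_proximal
  role: reactive_complex
  cycle: A
  conformer: proximal
  g_rel: 1.0
- name: RC1b_distal
  role: reactive_complex
  cycle: B
  conformer: distal
  g_rel: 2.2
- name: TS1a_proximal_2R1S
  role: transition_state
  cycle: A
  conformer: proximal
  g_rel: 14.0
  face_pair: Si,Si
  product_config: 2R,1'S
- name: TS1a_proximal_2S1R
  role: transition_state
  cycle: A
  conformer: proximal
  g_rel: 16.2
  face_pair: Re,Re
  product_config: 2S,1'R
- name: TS1a_proximal_2R1R
  role: transition_state
  cycle: A
  conformer: proximal
  g_rel: 15.6
  face_pair: Si,Re
  product_config: 2R,1'R
- name: TS1a_proximal_2S1S
  role: transition_state
  cycle: A
  conformer: proximal
  g_rel: 16.8
  face_pair: Re,Si
  product_config: 2S,1'S
- name: TS1b_distal_2R1S
  role: transition_state
  cycle: B
  conformer: distal
  g_rel: 14.2
  face_pair: Si,Si
  product_config: 2R,1'S
- name: TS1b_distal_2R1R
  role: transition_state
  cycle: B
  conformer: distal
  g_rel: 15.8
  face_pair: Si,Re
  product_config: 2R,1'R
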