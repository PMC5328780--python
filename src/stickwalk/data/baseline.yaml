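# Calibrated baseline configuration of the three-leg walking model.
# Conductances are in leak units (g_L = 1), times in ms, angles in degrees.
schema: 1
mode: tetrapod
sim:
  dt_ms: 0.1
  record_dt_ms: 1.0
neuron:
  cpg: {C: 20.0, g_L: 1.0, E_L: -65.0, g_P: 2.0, E_P: 40.0,
        theta_m: -44.0, sigma_m: 4.0, theta_h: -55.0, sigma_h: 4.0,
        tau_h0: 2500.0}
  # PR/EF half-centers act as sensory-gated switches; a weaker regenerative
  # current keeps them from free-running against the gate
  pr_ef_g_P: 0.8
  # prothoracic LD pair: deeper slow-variable setpoint and faster recovery
  # -> the front leg is excitable only, stepping on the rebound that follows
  # release of the intersegmental inhibition, and resting grounded when
  # uncoupled
  cpg_pro: {theta_h: -59.0, sigma_h: 4.0, tau_h0: 1500.0}
  cpg_pro_lev: {tau_h0: 1100.0}
  cpg_pro_dep: {theta_h: -63.0}
  # mesothoracic levator: faster recovery so the middle leg follows the
  # short tripod cycle one-for-one
  cpg_meso_lev: {tau_h0: 1400.0}
  passive: {C: 10.0, g_L: 1.0, E_L: -65.0}
  output: {theta_s: -40.0, sigma_s: 3.0}
  E_inh: -80.0
synapses:
  g_c: 3.0        # mutual inhibition within the PR and EF half-center pairs
  g_c_ld: 3.0     # mutual inhibition within the LD pair
  g_ci: 2.0       # CPG neuron -> premotor IN of the antagonist motoneuron
  g_im: 4.0       # premotor IN -> motoneuron (inhibitory)
  g_td: 1.2       # touch-down trigger IN -> depressor CPG neuron
  g_lo: 0.0       # lift-off trigger IN -> levator CPG neuron (off by default)
drives:
  g_MN: 2.0       # uniform excitatory input to all motoneurons
  g_b: 1.0        # tonic excitatory bias of every premotor IN
  g_d0: 1.2       # baseline inhibitory input to every premotor IN
modes:
  # central drives to the levator/depressor CPG neurons per segment;
  # FL (g_app3/4) is excitable, not self-oscillatory: its steps are
  # triggered by post-inhibitory rebound at release of the intersegmental
  # inhibition
  tetrapod: {g_app3: 0.16, g_app4: 0.07, g_app9: 0.10, g_app10: 0.06,
             g_app15: 0.1425, g_app16: 0.06}
  tripod:   {g_app3: 0.16, g_app4: 0.07, g_app9: 0.17, g_app10: 0.18,
             g_app15: 0.156, g_app16: 0.10}
intersegmental:
  g_inh3: 12.0    # onto the front leg LD CPG (C3-C4), from beta_ML
  g_inh9: 12.0    # onto the middle leg LD CPG (C9-C10), from beta_HL
  g_dep_factor: 1.0  # depressor-branch strength relative to the levator branch
  E_dep: -65.0       # depressor branch is shunting (reversal at rest)
  map_thr: 45.0   # deg; sigmoid threshold of the beta mapping
  map_slope: 2.0  # deg
  tau_rec: 6000.0 # ms; synaptic resource recovery
  tau_dep: 20000.0 # ms; (weak) activity-dependent depression
load:
  g_dep: 0.0      # optional drive to the depressor CPG neuron while grounded
  g_lev: 0.05     # load inhibition of the levator CPG neuron (anti-swing)
  tau_ms: 80.0    # onset/offset lag of the load signal
gates:
  beta_pr_thresh: 33.0   # ground contact: stance/retraction initiation
  beta_ef_thresh: 45.0   # earlier, higher threshold: flexion initiation
  g_gate: 0.8
sensors:
  alpha_td_thresh: 35.0  # protraction-complete trigger (touch-down)
  alpha_lo_thresh: 120.0 # retraction-complete trigger (lift-off)
  tau_pulse_ms: 40.0
  g_pulse: 3.0
  g_park: 0.15           # swing-end reflex onto the depressor CPG neuron
  beta_park: 50.0        # elevation above which the reflex can engage
  g_ground: 0.4          # ground-proximity reflex onto the depressor MN
muscles:
  tau_act_ms: 25.0
  gain_alpha: 0.85  # deg/ms at full differential activation
  gain_beta: 0.8
  gain_gamma: 0.45
angles:
  alpha: [28.0, 128.0]
  beta: [30.0, 60.0]
  gamma: [45.0, 110.0]
decoupling:
  strong_factor: 5.0   # "strong" drive change = 5 x baseline g_app
  g_d_strong: 5.0      # strong inhibition of a premotor IN
  g_exc_const: 2.0     # constant excitatory override of an intersegmental synapse
  # calibrated front-leg drive-decoupling command (excite levator C3,
  # inhibit depressor C4); chosen so that both outcomes of the command
  # (permanent lift vs continued stepping) coexist, phase-dependently
  fl_drive_command: {g_exc: 0.58, g_inh: 0.10}
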