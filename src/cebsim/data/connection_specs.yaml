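version: 1
connection_types:
- name: mf_glom
  pre_population: mf
  post_population: glom
  convergence: 1
  synapse_weight: 1.0
  delay: 1.0
  receptor_time_constant: 1.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: glom_GrC
  pre_population: glom
  post_population: GrC
  convergence: 4
  synapse_weight: 0.2
  delay: 1.0
  receptor_time_constant: 2.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.05
  synapse_weight_upbound: null
- name: glom_GoC
  pre_population: glom
  post_population: GoC
  convergence: 50
  synapse_weight: 0.1
  delay: 1.0
  receptor_time_constant: 2.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.1
  synapse_weight_upbound: null
- name: GoC_GrC
  pre_population: GoC
  post_population: GrC
  convergence: 2
  synapse_weight: -0.6
  delay: 2.0
  receptor_time_constant: 10.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.1
  synapse_weight_upbound: null
- name: GoC_GoC
  pre_population: GoC
  post_population: GoC
  convergence: 4
  synapse_weight: -0.3
  delay: 1.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: GrC_aa_GoC
  pre_population: GrC
  post_population: GoC
  convergence: 100
  synapse_weight: 0.1
  delay: 2.0
  receptor_time_constant: 2.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.05
  synapse_weight_upbound: null
- name: GrC_pf_GoC
  pre_population: GrC
  post_population: GoC
  convergence: 400
  synapse_weight: 0.05
  delay: 5.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: GrC_aa_PC
  pre_population: GrC
  post_population: PC
  convergence: 50
  synapse_weight: 0.08
  delay: 2.0
  receptor_time_constant: 2.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.05
  synapse_weight_upbound: null
- name: GrC_pf_PC
  pre_population: GrC
  post_population: PC
  convergence: 1000
  synapse_weight: 0.16
  delay: 5.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: true
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: GrC_pf_SC
  pre_population: GrC
  post_population: SC
  convergence: 300
  synapse_weight: 0.03
  delay: 5.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: true
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: GrC_pf_BC
  pre_population: GrC
  post_population: BC
  convergence: 300
  synapse_weight: 0.03
  delay: 5.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: true
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: SC_PC
  pre_population: SC
  post_population: PC
  convergence: 10
  synapse_weight: -0.25
  delay: 1.0
  receptor_time_constant: 10.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.15
  synapse_weight_upbound: null
- name: BC_PC
  pre_population: BC
  post_population: PC
  convergence: 10
  synapse_weight: -0.25
  delay: 1.0
  receptor_time_constant: 10.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.15
  synapse_weight_upbound: null
- name: SC_SC
  pre_population: SC
  post_population: SC
  convergence: 4
  synapse_weight: -0.2
  delay: 1.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.15
  synapse_weight_upbound: null
- name: BC_BC
  pre_population: BC
  post_population: BC
  convergence: 4
  synapse_weight: -0.2
  delay: 1.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: 0.15
  synapse_weight_upbound: null
- name: mf_DCN_p
  pre_population: mf
  post_population: DCN_p
  convergence: 20
  synapse_weight: 0.15
  delay: 4.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 2
  plastic: false
  micromodule_confined: false
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: IO_DCN_p
  pre_population: IO
  post_population: DCN_p
  convergence: 1
  synapse_weight: 4.0
  delay: 4.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: true
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: PC_DCN_p
  pre_population: PC
  post_population: DCN_p
  convergence: 25
  synapse_weight: -0.8
  delay: 4.0
  receptor_time_constant: 10.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: true
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: -4.1
- name: PC_DCN_GABA
  pre_population: PC
  post_population: DCN_GABA
  convergence: 25
  synapse_weight: -0.6
  delay: 4.0
  receptor_time_constant: 10.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: true
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: -3.1
- name: IO_DCN_GABA
  pre_population: IO
  post_population: DCN_GABA
  convergence: 1
  synapse_weight: 0.8
  delay: 4.0
  receptor_time_constant: 5.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: true
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: IO_PC
  pre_population: IO
  post_population: PC
  convergence: 1
  synapse_weight: 80.0
  delay: 4.0
  receptor_time_constant: 1.5
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: true
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
- name: IO_SC
  pre_population: IO
  post_population: SC
  convergence: 2
  synapse_weight: 1.0
  delay: 4.0
  receptor_time_constant: 1.5
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: true
  local_radius: null
  synapse_weight_upbound: null
- name: IO_BC
  pre_population: IO
  post_population: BC
  convergence: 2
  synapse_weight: 1.0
  delay: 4.0
  receptor_time_constant: 1.5
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: false
  sagittal_gradient: true
  local_radius: null
  synapse_weight_upbound: null
- name: DCN_GABA_IO
  pre_population: DCN_GABA
  post_population: IO
  convergence: 4
  synapse_weight: -0.3
  delay: 20.0
  receptor_time_constant: 30.0
  n_contacts_per_pair: 1
  plastic: false
  micromodule_confined: true
  sagittal_gradient: false
  local_radius: null
  synapse_weight_upbound: null
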