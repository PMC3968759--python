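sample_id,treatment,port,fe_total_mean,fe_total_sd,fe_total_n,fe2_ferrozine_mean,fe2_ferrozine_sd,fe2_ferrozine_n,fe_dcb_mean,fe_dcb_sd,fe_dcb_n,fe_aod_mean,fe_aod_sd,fe_aod_n,s_avs_mean,s_avs_sd,s_avs_n,s_crr_mean,s_crr_sd,s_crr_n,p_febound_mean,p_febound_sd,p_febound_n,fe_fes_mean,fe_fes_sd,fe_fes_n,fe_pyrite_mean,fe_pyrite_sd,fe_pyrite_n,fe_siderite_mean,fe_siderite_sd,fe_siderite_n,fe_vivianite_mean,fe_vivianite_sd,fe_vivianite_n
initial,initial,,2.24,0.13,2,0.48,0.02,3,1.53,0.04,2,1.11,0.11,2,0.05,0.00,2,0.34,0.05,3,0.018,0.001,4,,,,,,,0,0,1,,,
U2,unamended,2,2.13,0.28,2,0.28,0.09,3,1.30,0.02,2,0.80,0.05,2,,,,,,,,,,0.042,0.001,2,0.399,0.087,3,0.52,0,3,0.00066,0.00015,3
U3,unamended,3,2.23,0.14,2,0.47,0.04,3,1.76,0.08,2,0.88,0.03,2,,,,,,,,,,0.039,0.006,2,0.427,0.011,3,0.53,0,3,0.00060,0.00002,3
A2,amended,2,2.67,0.10,2,0.30,0.04,3,0.94,0.05,2,0.72,0.10,2,,,,,,,,,,0.115,0.011,2,0.421,0.032,3,0.17,0,3,0.00149,0.00071,3
A3,amended,3,3.20,0.01,2,0.21,0.02,3,1.49,0.10,2,0.75,0.03,2,,,,,,,,,,0.095,0.007,2,0.407,0.142,3,0.43,0,3,0.00087,0.00004,3
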