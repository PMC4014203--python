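case,sgac_pass_pct,mgac_uncorrected_pass_pct,mgac_corrected_pass_pct,global_3d_pass_pct,PTVnx_pass_pct,PTV1_pass_pct,PTV2_pass_pct,Brainstem_pass_pct,SpinalCord_pass_pct,OpticChiasm_pass_pct,OpticNerve_L_pass_pct,OpticNerve_R_pass_pct,Parotid_L_pass_pct,Parotid_R_pass_pct
case_shift,99.0000,95.0000,99.0000,99.9566,100.0000,99.7976,99.8935,100.0000,100.0000,100.0000,100.0000,100.0000,100.0000,100.0000
case_scale,100.0000,100.0000,100.0000,99.8480,100.0000,100.0000,99.6273,100.0000,100.0000,100.0000,100.0000,100.0000,100.0000,100.0000
case_blur,100.0000,94.0000,100.0000,99.5656,100.0000,100.0000,99.3610,96.4103,100.0000,100.0000,100.0000,100.0000,100.0000,100.0000
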