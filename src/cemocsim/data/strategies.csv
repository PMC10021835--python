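id,access_param,target_cs_rate,hist_cs_param
A_national,p_access_national,0.172,p_hist_cs_national
B_rural,p_access_rural,0.128,p_hist_cs_rural
C_urban,p_access_urban,0.282,p_hist_cs_urban
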