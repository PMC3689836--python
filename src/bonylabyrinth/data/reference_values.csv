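target_id,mode,expected,tolerance,gating
ratio_7595_ant,abs,0.00,0.0001,exact
ratio_7595_lat,abs,0.00,0.0001,exact
ratio_7595_pos,abs,0.00,0.0001,exact
ratio_8261_ant,abs,0.38,0.0001,exact
ratio_8261_lat,abs,0.00,0.0001,exact
ratio_8261_pos,abs,0.44,0.0001,exact
ratio_8265_ant,abs,0.17,0.0001,exact
ratio_8265_lat,abs,0.00,0.0001,exact
ratio_8265_pos,abs,0.36,0.0001,exact
ratio_7536_ant,abs,0.58,0.0001,exact
ratio_7536_lat,abs,0.26,0.0001,exact
ratio_7536_pos,abs,0.29,0.0001,exact
ratio_8266_ant,abs,0.58,0.0001,exact
ratio_8266_lat,abs,0.26,0.0001,exact
ratio_8266_pos,abs,0.37,0.0001,exact
ratio_7539_ant,abs,0.00,0.0001,exact
ratio_7539_lat,abs,0.00,0.0001,exact
ratio_7539_pos,abs,0.45,0.0001,exact
ratio_7542_ant,abs,0.35,0.0001,exact
ratio_7542_lat,abs,0.00,0.0001,exact
ratio_7542_pos,abs,0.24,0.0001,exact
ratio_8267_ant,abs,0.41,0.0001,exact
ratio_8267_lat,abs,0.26,0.0001,exact
ratio_8267_pos,abs,0.27,0.0001,exact
ratio_7545_ant,abs,0.59,0.0001,exact
ratio_7545_lat,abs,0.20,0.0001,exact
ratio_7545_pos,abs,0.33,0.0001,exact
ratio_8268_ant,abs,0.65,0.0001,exact
ratio_8268_lat,abs,0.20,0.0001,exact
ratio_8268_pos,abs,0.45,0.0001,exact
ratio_8273_ant,abs,0.48,0.0001,exact
ratio_8273_lat,abs,0.35,0.0001,exact
ratio_8273_pos,abs,0.38,0.0001,exact
ratio_7599_ant,abs,0.39,0.0001,exact
ratio_7599_lat,abs,0.30,0.0001,exact
ratio_7599_pos,abs,0.27,0.0001,exact
mass_canis_kg,abs,4.5,0.05,exact
mass_bathygenys_kg,abs,2.5,0.05,exact
mass_balaenopterid_kg,abs,1608.3,32.2,tolerance
regression_slope,abs,0.151,0.0005,exact
regression_intercept,abs,0.8212,0.02,tolerance
r_length_mass,abs,0.94,0.05,tolerance
r_volume_mass,abs,0.95,0.05,tolerance
r_coiling_mass,abs,0.02,0.05,tolerance
cochlear_pct_didelphis,abs,69,0.0001,exact
cochlear_pct_hemicentetes,abs,50,0.0001,exact
cochlear_pct_chrysochloris,abs,71,0.0001,exact
didelphis_lateral_deviation_ratio,abs,1.27,0.0001,exact
angular_deviation_within_0p6_share,ge,0.80,0,tolerance
contrast_welch_p,abs,0.007,0.014,qualitative
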