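specimen_id,lindev_ant_mm,lindev_lat_mm,lindev_post_mm,lumen_ant_mm,lumen_lat_mm,lumen_post_mm
TMM M-7595,0.00,0.00,0.00,0.20,0.27,0.26
TMM M-8261,0.08,0.00,0.08,0.21,0.24,0.18
TMM M-8265,0.05,0.00,0.08,0.29,0.25,0.22
TMM M-7536,0.11,0.05,0.07,0.19,0.19,0.24
TMM M-8266,0.11,0.05,0.07,0.19,0.19,0.19
TMM M-7539,0.00,0.00,0.10,0.21,0.19,0.22
TMM M-7542,0.08,0.00,0.06,0.23,0.22,0.25
TMM M-8267,0.07,0.05,0.06,0.17,0.19,0.22
TMM M-7545,0.10,0.05,0.09,0.17,0.25,0.27
TMM M-8268,0.11,0.04,0.09,0.17,0.20,0.20
TMM M-8273,0.11,0.07,0.09,0.23,0.20,0.24
TMM M-7599,0.07,0.06,0.07,0.18,0.20,0.26
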