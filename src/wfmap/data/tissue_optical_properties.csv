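wavelength_nm,tissue,mu_a_mm,mu_s_mm,g
470,skull,0.1137,28.10,0.920
530,skull,0.1137,25.99,0.920
590,skull,0.0750,24.24,0.920
625,skull,0.0424,23.35,0.920
730,skull,0.0274,21.11,0.920
850,skull,0.0172,19.12,0.920
470,gray,0.465,11.63,0.882
530,gray,0.638,10.53,0.887
590,gray,0.287,9.62,0.892
625,gray,0.032,9.15,0.895
730,gray,0.009,8.12,0.899
850,gray,0.016,7.24,0.898
470,white,0.465,42.85,0.790
530,white,0.638,41.94,0.810
590,white,0.287,40.70,0.830
625,white,0.032,40.28,0.836
730,white,0.009,38.61,0.858
850,white,0.016,35.31,0.871
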