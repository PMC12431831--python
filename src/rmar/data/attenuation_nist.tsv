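# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV),
# standard reference values (NIST XCOM / ICRU-44 cortical bone), with
# coherent scattering included.  Log-log linear interpolation is used
# between grid points.
# columns: material	energy_kev	mu_over_rho_cm2_g
water	20	0.8096
water	30	0.3756
water	40	0.2683
water	50	0.2269
water	60	0.2059
water	80	0.1837
water	100	0.1707
water	150	0.1505
water	200	0.1370
bone	20	4.001
bone	30	1.331
bone	40	0.6655
bone	50	0.4242
bone	60	0.3148
bone	80	0.2229
bone	100	0.1855
bone	150	0.1480
bone	200	0.1309
titanium	20	15.85
titanium	30	4.972
titanium	40	2.214
titanium	50	1.213
titanium	60	0.7661
titanium	80	0.4052
titanium	100	0.2721
titanium	150	0.1649
titanium	200	0.1314
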