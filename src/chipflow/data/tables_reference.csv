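table,chip_width_um,v_inlet_m_s,shear_dyn_cm2,vel_m_s
avg,40,0.001536,0.18811,4.91e-04
avg,40,0.003073,0.37625,9.82e-04
avg,40,0.006145,0.75238,0.001963
avg,40,0.012291,1.5049,0.0039264
avg,40,0.024582,3.0098,0.0078528
avg,40,0.04097,5.0163,0.013088
avg,25,0.002458,0.49106,7.27e-04
avg,25,0.004916,0.98211,0.0014538
avg,25,0.009833,1.9644,0.0029079
avg,25,0.019666,3.9288,0.0058158
avg,25,0.039331,7.8575,0.011631
avg,25,0.065552,13.096,0.019386
max,40,0.001536,115.79,0.0042421
max,40,0.003073,231.59,0.0084848
max,40,0.006145,463.1,0.016967
max,40,0.012291,926.28,0.033936
max,40,0.024582,1852.6,0.067873
max,40,0.04097,3087.6,0.11312
max,25,0.002458,115.9,0.0041847
max,25,0.004916,231.81,0.0083694
max,25,0.009833,463.67,0.01674
max,25,0.019666,927.33,0.033481
max,25,0.039331,1854.6,0.06696
max,25,0.065552,3091,0.1116
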