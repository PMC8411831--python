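# Complex refractive index of gold (evaporated films).
# Source: P. B. Johnson and R. W. Christy, Phys. Rev. B 6, 4370 (1972), Table 1.
# Photon energies converted to vacuum wavelength via lambda_nm = 1239.84193 / E_eV.
# columns: wavelength_nm n k
   354.241   1.500   1.8660
   367.906   1.480   1.8950
   381.490   1.460   1.9330
   397.385   1.470   1.9520
   413.281   1.460   1.9580
   430.501   1.450   1.9480
   450.852   1.380   1.9140
   471.423   1.310   1.8490
   495.937   1.040   1.8330
   520.942   0.620   2.0810
   548.603   0.430   2.4550
   582.085   0.290   2.8630
   616.837   0.210   3.2720
   659.490   0.140   3.6970
   704.456   0.130   4.1030
   756.001   0.140   4.5420
   821.087   0.160   5.0830
   891.973   0.170   5.6630
   984.002   0.220   6.3500
  1087.581   0.270   7.1500
  1215.531   0.350   8.1450
  1393.081   0.430   9.5190
  1610.184   0.560  11.2100
  1937.253   0.920  13.7800
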