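# Gold complex dielectric function eps = eps_real + i*eps_imag,
# from the Johnson & Christy (1972) n,k measurements, 0.64-3.00 eV.
wavelength_nm,eps_real,eps_imag
413.281,-1.702164,5.717360
430.501,-1.692204,5.649200
450.852,-1.758996,5.282640
471.423,-1.702701,4.844380
495.937,-2.278289,3.812640
520.942,-3.946161,2.580440
548.603,-5.842125,2.111300
582.085,-8.112669,1.660540
616.837,-10.661884,1.374240
659.490,-13.648209,1.035160
704.456,-16.817709,1.066780
756.001,-20.610164,1.271760
821.087,-25.811289,1.626560
891.973,-32.040669,1.925420
984.002,-40.274100,2.794000
1087.581,-51.049600,3.861000
1215.531,-66.218525,5.701500
1393.081,-90.426461,8.186340
1610.184,-125.350500,12.555200
1937.253,-189.042000,25.355200
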