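element,ionization,wavelength_nm,fwhm_nm,signal_halfwidth_nm,bg_lo_start,bg_lo_end,bg_hi_start,bg_hi_end
C,I,247.856,0.06,0.30,246.956,247.356,248.356,248.756
Mn,II,257.610,0.06,0.30,256.710,257.110,258.110,258.510
Fe,II,259.940,0.06,0.30,259.040,259.440,260.440,260.840
Fe,II,274.640,0.06,0.30,273.740,274.140,275.140,275.540
Mg,II,279.550,0.06,0.30,278.650,279.050,280.650,281.050
Mg,II,280.270,0.06,0.30,278.650,279.050,280.770,281.170
Mg,I,285.213,0.06,0.30,284.313,284.713,285.713,286.113
Si,I,288.150,0.06,0.30,287.250,287.650,288.650,289.050
Al,I,309.270,0.06,0.30,308.370,308.770,309.770,310.170
Cu,I,324.750,0.06,0.30,323.850,324.250,325.250,325.650
Ca,II,393.360,0.12,0.30,392.160,392.560,395.100,395.500
Al,I,394.400,0.12,0.30,391.900,392.300,395.100,395.500
Ca,I,422.670,0.12,0.30,421.770,422.170,423.170,423.570
Ca,I,442.540,0.12,0.30,441.640,442.040,444.190,444.590
Ca,I,443.590,0.12,0.30,441.640,442.040,444.190,444.590
Na,I,588.995,0.12,0.30,587.700,588.100,590.490,590.890
Na,I,589.590,0.12,0.30,587.700,588.100,590.490,590.890
Ca,I,610.270,0.12,0.30,609.370,609.770,610.770,611.170
Ca,I,612.220,0.12,0.30,611.320,611.720,612.720,613.120
Ca,I,643.900,0.12,0.30,643.000,643.400,644.400,644.800
K,I,766.490,0.12,0.30,765.590,765.990,766.990,767.390
K,I,769.900,0.12,0.30,769.000,769.400,770.400,770.800
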