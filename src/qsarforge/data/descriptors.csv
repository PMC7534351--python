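compound,pIC50_V600E,pIC50_RAF1,IW1,IW2,FLEX,PSA,ACDODO,DD8
1b,6.611,-,0.031,0.081,3.740,122.660,12.117,0.250
1e,6.842,-,0.045,0.112,2.772,99.200,7.005,1.500
1f,7.077,-,0.049,0.126,2.834,99.200,7.135,0.125
1h,6.719,-,0.040,0.092,3.433,122.060,7.896,0.000
1i,6.848,-,0.024,0.054,3.577,122.060,7.773,0.375
1j,7.107,-,0.033,0.077,3.048,119.430,14.874,0.875
1m,7.083,-,0.012,0.028,4.289,119.940,6.937,0.625
1n,6.921,-,0.011,0.021,4.106,119.840,8.935,2.875
1r,7.951,7.341,0.033,0.087,3.748,126.060,26.359,0.000
1s,7.735,7.304,0.017,0.056,4.217,131.160,25.881,1.750
1t,6.712,-,0.046,0.118,4.984,136.260,23.780,0.250
1u,7.346,-,0.027,0.078,3.353,105.230,6.998,0.250
1v,7.000,-,0.024,0.066,3.592,116.660,6.230,0.500
1w,6.917,-,0.037,0.095,4.087,110.330,5.902,0.250
1z,6.618,-,0.025,0.065,4.241,125.870,6.422,0.250
1zb,9.010,8.086,0.027,0.075,3.237,114.030,23.318,1.000
1zc,8.721,7.979,0.018,0.047,3.510,134.260,25.265,0.000
1zd,8.469,7.777,0.013,0.044,3.874,119.130,16.949,0.000
1ze,7.541,6.330,0.048,0.108,3.975,124.230,25.509,1.625
1zf,7.654,6.821,0.021,0.061,4.241,134.770,23.943,0.250
1zg,7.801,6.801,0.020,0.045,4.350,134.670,28.806,2.750
1zh,8.131,7.206,0.018,0.041,4.085,134.670,23.955,0.500
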