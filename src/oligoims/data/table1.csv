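species,n,z,mz_B,M_B,tD_B,omega_B,mz_A,M_A,tD_A,omega_A,delta_printed
DIMER,2,3,2887.05,8658.15,17.20,1018.1,2886.88,8657.64,17.20,1018.1,-0.51
DIMER,2,4,2165.82,8659.28,10.36,975.4,2165.69,8658.76,10.36,975.4,-0.52
DIMER,2,5,1732.90,8659.50,10.70,1245.1,1732.91,8659.55,10.70,1245.1,0.05
DIMER,2,5,1732.91,8659.55,10.15,1203,1732.92,8659.60,10.15,1203,0.05
DIMER,2,5,1732.90,8659.50,7.39,979,1732.62,8658.10,7.39,979,-1.4
DIMER,2,6,1444.28,8659.68,9.37,1370,1444.28,8659.68,9.37,1370,0
DIMER,2,6,,8659.68,,,1443.93,8657.58,7.50,1185,-2.1
DIMER,2,7,1238.09,8659.63,8.16,1460,1238.10,8659.70,8.16,1460,0.07
DIMER,2,7,1238.07,8659.49,7.60,1394.7,1237.82,8657.74,6.95,1315,-1.89
DIMER,2,8,1083.47,8659.76,6.28,1407.5,1083.46,8659.68,6.28,1407.5,-0.08
DIMER,2,8,,8659.76,,,1083.26,8658.08,7.17,1534.5,-1.68
DIMER,2,9,,8659.76,,,962.97,8657.73,6.06,1547,-2.03
TRIMER,3,4,3247.38,12985.52,16.60,1326,3247.19,12984.76,16.60,1326,-0.76
TRIMER,3,5,2598.63,12988.15,11.25,1286.5,2598.44,12987.20,11.25,1286.5,-0.95
TRIMER,3,6,2165.79,12988.75,12.30,1636.3,2165.69,12988.14,12.30,1636.3,-0.60
TRIMER,3,6,2165.82,12988.92,8.60,1295.8,2165.60,12987.60,8.60,1295.8,-1.32
TRIMER,3,7,1856.60,12989.20,12.20,1898.9,1856.59,12989.13,12.0,1878.5,-0.07
TRIMER,3,7,1856.58,12989.06,10.25,1695,1856.41,12988.15,10.14,1683,-1.19
TRIMER,3,7,,12989.06,,,1856.07,12985.45,8.36,1484,-3.57
TRIMER,3,7,,12989.06,,,1856.04,12985.28,7.60,1394.7,-3.78
TRIMER,3,8,1624.67,12989.36,11.03,2032.1,1624.68,12989.44,11.03,2032.1,0.08
TRIMER,3,8,1624.68,12989.44,10.25,1937,1624.45,12987.60,9.70,1868.7,-1.84
TRIMER,3,8,,12989.44,,,1624.43,12987.44,9.04,1784.8,-2.00
TRIMER,3,8,,12989.44,,,1624.18,12985.44,7.64,1599.4,-4.00
TRIMER,3,10,1299.92,12989.20,9.04,2231,1299.77,12987.70,8.05,2068.6,-1.50
TRIMER,3,10,,12989.20,,,1299.53,12985.30,7.17,1918,-3.90
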