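w1,T_K,x3,u_x3
0.00,278.15,1.360e-4,0.024e-4
0.00,283.15,1.767e-4,0.015e-4
0.00,288.15,2.2e-4,0.03e-4
0.00,293.15,2.74e-4,0.06e-4
0.00,298.15,3.41e-4,0.10e-4
0.00,303.15,4.09e-4,0.09e-4
0.00,308.15,4.95e-4,0.04e-4
0.00,313.15,6.36e-4,0.11e-4
0.00,318.15,7.49e-4,0.14e-4
0.05,278.15,1.505e-4,0.024e-4
0.05,283.15,1.94e-4,0.05e-4
0.05,288.15,2.412e-4,0.026e-4
0.05,293.15,3.01e-4,0.07e-4
0.05,298.15,3.831e-4,0.032e-4
0.05,303.15,4.45e-4,0.04e-4
0.05,308.15,5.45e-4,0.06e-4
0.05,313.15,7.06e-4,0.21e-4
0.05,318.15,8.26e-4,0.17e-4
0.10,278.15,1.69e-4,0.04e-4
0.10,283.15,2.14e-4,0.06e-4
0.10,288.15,2.66e-4,0.07e-4
0.10,293.15,3.4e-4,0.05e-4
0.10,298.15,4.19e-4,0.04e-4
0.10,303.15,4.97e-4,0.1e-4
0.10,308.15,5.92e-4,0.11e-4
0.10,313.15,7.69e-4,0.14e-4
0.10,318.15,9.08e-4,0.18e-4
0.15,278.15,1.92e-4,0.016e-4
0.15,283.15,2.386e-4,0.022e-4
0.15,288.15,2.974e-4,0.021e-4
0.15,293.15,3.69e-4,0.05e-4
0.15,298.15,4.54e-4,0.06e-4
0.15,303.15,5.38e-4,0.11e-4
0.15,308.15,6.52e-4,0.07e-4
0.15,313.15,8.49e-4,0.21e-4
0.15,318.15,10.15e-4,0.19e-4
0.20,278.15,2.13e-4,0.03e-4
0.20,283.15,2.634e-4,0.023e-4
0.20,288.15,3.30e-4,0.08e-4
0.20,293.15,4.07e-4,0.09e-4
0.20,298.15,4.93e-4,0.06e-4
0.20,303.15,5.93e-4,0.06e-4
0.20,308.15,7.38e-4,0.12e-4
0.20,313.15,9.28e-4,0.25e-4
0.20,318.15,11.11e-4,0.2e-4
0.25,278.15,2.386e-4,0.008e-4
0.25,283.15,2.99e-4,0.04e-4
0.25,288.15,3.66e-4,0.09e-4
0.25,293.15,4.6e-4,0.08e-4
0.25,298.15,5.48e-4,0.11e-4
0.25,303.15,6.61e-4,0.09e-4
0.25,308.15,8.08e-4,0.22e-4
0.25,313.15,10.23e-4,0.17e-4
0.25,318.15,12.36e-4,0.31e-4
0.30,278.15,2.66e-4,0.04e-4
0.30,283.15,3.30e-4,0.06e-4
0.30,288.15,4.02e-4,0.06e-4
0.30,293.15,5.00e-4,0.08e-4
0.30,298.15,5.89e-4,0.04e-4
0.30,303.15,7.14e-4,0.13e-4
0.30,308.15,8.81e-4,0.23e-4
0.30,313.15,11.34e-4,0.31e-4
0.30,318.15,13.9e-4,0.26e-4
0.35,278.15,3.04e-4,0.05e-4
0.35,283.15,3.69e-4,0.07e-4
0.35,288.15,4.56e-4,0.09e-4
0.35,293.15,5.53e-4,0.04e-4
0.35,298.15,6.68e-4,0.07e-4
0.35,303.15,8.00e-4,0.11e-4
0.35,308.15,9.71e-4,0.09e-4
0.35,313.15,12.4e-4,0.3e-4
0.35,318.15,15.12e-4,0.26e-4
0.40,278.15,3.41e-4,0.04e-4
0.40,283.15,4.145e-4,0.033e-4
0.40,288.15,4.96e-4,0.10e-4
0.40,293.15,6.20e-4,0.05e-4
0.40,298.15,7.33e-4,0.15e-4
0.40,303.15,8.58e-4,0.10e-4
0.40,308.15,10.62e-4,0.07e-4
0.40,313.15,13.64e-4,0.22e-4
0.40,318.15,16.9e-4,0.4e-4
0.45,278.15,3.78e-4,0.08e-4
0.45,283.15,4.61e-4,0.09e-4
0.45,288.15,5.56e-4,0.07e-4
0.45,293.15,6.709e-4,0.022e-4
0.45,298.15,8.06e-4,0.15e-4
0.45,303.15,9.67e-4,0.19e-4
0.45,308.15,11.93e-4,0.18e-4
0.45,313.15,15.0e-4,0.4e-4
0.45,318.15,18.59e-4,0.29e-4
0.50,278.15,4.28e-4,0.05e-4
0.50,283.15,5.08e-4,0.06e-4
0.50,288.15,6.08e-4,0.06e-4
0.50,293.15,7.38e-4,0.05e-4
0.50,298.15,8.69e-4,0.13e-4
0.50,303.15,10.62e-4,0.03e-4
0.50,308.15,12.9e-4,0.06e-4
0.50,313.15,16.5e-4,0.4e-4
0.50,318.15,20.5e-4,0.4e-4
0.55,278.15,4.69e-4,0.008e-4
0.55,283.15,5.63e-4,0.13e-4
0.55,288.15,6.92e-4,0.02e-4
0.55,293.15,8.19e-4,0.2e-4
0.55,298.15,9.71e-4,0.11e-4
0.55,303.15,11.57e-4,0.19e-4
0.55,308.15,14.6e-4,0.4e-4
0.55,313.15,18.17e-4,0.19e-4
0.55,318.15,22.8e-4,0.7e-4
0.60,278.15,5.26e-4,0.04e-4
0.60,283.15,6.32e-4,0.11e-4
0.60,288.15,7.567e-4,0.027e-4
0.60,293.15,9.14e-4,0.19e-4
0.60,298.15,10.81e-4,0.15e-4
0.60,303.15,12.64e-4,0.27e-4
0.60,308.15,15.8e-4,0.4e-4
0.60,313.15,20.1e-4,0.3e-4
0.60,318.15,25.3e-4,0.6e-4
0.65,278.15,6.03e-4,0.06e-4
0.65,283.15,7.06e-4,0.09e-4
0.65,288.15,8.45e-4,0.25e-4
0.65,293.15,9.95e-4,0.04e-4
0.65,298.15,11.87e-4,0.30e-4
0.65,303.15,13.92e-4,0.4e-4
0.65,308.15,17.69e-4,0.2e-4
0.65,313.15,21.7e-4,0.14e-4
0.65,318.15,28.31e-4,0.35e-4
0.70,278.15,6.62e-4,0.07e-4
0.70,283.15,7.93e-4,0.10e-4
0.70,288.15,9.28e-4,0.26e-4
0.70,293.15,11.06e-4,0.22e-4
0.70,298.15,13.12e-4,0.16e-4
0.70,303.15,15.3e-4,0.27e-4
0.70,308.15,19.05e-4,0.09e-4
0.70,313.15,24.0e-4,0.5e-4
0.70,318.15,31.5e-4,0.5e-4
0.75,278.15,7.45e-4,0.16e-4
0.75,283.15,8.74e-4,0.14e-4
0.75,288.15,10.132e-4,0.03e-4
0.75,293.15,12.14e-4,0.08e-4
0.75,298.15,14.13e-4,0.24e-4
0.75,303.15,16.7e-4,0.19e-4
0.75,308.15,21.67e-4,0.31e-4
0.75,313.15,27.0e-4,0.9e-4
0.75,318.15,34.4e-4,0.7e-4
0.80,278.15,8.30e-4,0.13e-4
0.80,283.15,9.84e-4,0.19e-4
0.80,288.15,11.62e-4,0.13e-4
0.80,293.15,13.16e-4,0.07e-4
0.80,298.15,15.6e-4,0.4e-4
0.80,303.15,18.8e-4,0.24e-4
0.80,308.15,23.87e-4,0.29e-4
0.80,313.15,30.0e-4,0.5e-4
0.80,318.15,37.8e-4,0.7e-4
0.85,278.15,9.30e-4,0.11e-4
0.85,283.15,10.84e-4,0.16e-4
0.85,288.15,12.91e-4,0.26e-4
0.85,293.15,15.07e-4,0.12e-4
0.85,298.15,17.07e-4,0.28e-4
0.85,303.15,20.56e-4,0.06e-4
0.85,308.15,25.9e-4,0.4e-4
0.85,313.15,32.2e-4,0.6e-4
0.85,318.15,42.1e-4,1.2e-4
0.90,278.15,10.59e-4,0.04e-4
0.90,283.15,12.1e-4,0.22e-4
0.90,288.15,14.03e-4,0.33e-4
0.90,293.15,16.46e-4,0.16e-4
0.90,298.15,19.0e-4,0.5e-4
0.90,303.15,22.51e-4,0.32e-4
0.90,308.15,28.6e-4,0.7e-4
0.90,313.15,35.7e-4,0.8e-4
0.90,318.15,46.7e-4,0.5e-4
0.95,278.15,11.84e-4,0.13e-4
0.95,283.15,13.58e-4,0.29e-4
0.95,288.15,15.43e-4,0.12e-4
0.95,293.15,18.37e-4,0.23e-4
0.95,298.15,20.6e-4,0.5e-4
0.95,303.15,24.88e-4,0.4e-4
0.95,308.15,31.9e-4,0.4e-4
0.95,313.15,39.5e-4,0.5e-4
0.95,318.15,52.9e-4,0.4e-4
1.00,278.15,13.09e-4,0.10e-4
1.00,283.15,15.10e-4,0.07e-4
1.00,288.15,17.40e-4,0.09e-4
1.00,293.15,20.09e-4,0.18e-4
1.00,298.15,22.86e-4,0.27e-4
1.00,303.15,27.14e-4,0.14e-4
1.00,308.15,34.7e-4,0.5e-4
1.00,313.15,43.9e-4,0.32e-4
1.00,318.15,57.2e-4,0.9e-4
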