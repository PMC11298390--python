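temperature_K,pressure_bar,solubility
308.15,160,2.21e-5
308.15,200,2.56e-5
308.15,240,2.87e-5
308.15,280,3.21e-5
308.15,320,3.45e-5
308.15,360,4.23e-5
308.15,400,4.56e-5
318.15,160,5.01e-5
318.15,200,6.58e-5
318.15,240,7.68e-5
318.15,280,9.01e-5
318.15,320,1.12e-4
318.15,360,1.03e-4
318.15,400,1.20e-4
328.15,160,7.01e-5
328.15,200,1.16e-4
328.15,240,1.75e-4
328.15,280,2.20e-4
328.15,320,2.54e-4
328.15,360,3.24e-4
328.15,400,3.59e-4
338.15,160,1.01e-4
338.15,200,2.45e-4
338.15,240,3.25e-4
338.15,280,4.92e-4
338.15,320,5.79e-4
338.15,360,6.87e-4
338.15,400,7.12e-4
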