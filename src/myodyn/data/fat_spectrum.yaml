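# Six-peak triglyceride spectral model for fat-water separation.
# Chemical shifts are relative to the water resonance (ppm); relative
# amplitudes are normalized at load time.  Values are the widely used
# in-vivo liver/muscle calibration; override via DixonProtocol to match
# a different tissue calibration.
peaks:
  - {shift_ppm: -3.80, amplitude: 0.087}
  - {shift_ppm: -3.40, amplitude: 0.693}
  - {shift_ppm: -2.60, amplitude: 0.128}
  - {shift_ppm: -1.94, amplitude: 0.004}
  - {shift_ppm: -0.39, amplitude: 0.039}
  - {shift_ppm:  0.60, amplitude: 0.048}
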