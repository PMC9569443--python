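# Default analysis settings; CLI flags and user YAML files override these.
tol_ppm: 10.0              # XIC m/z tolerance (ppm), every selection level
integration: trapezoid     # trapezoid | peak
loq_ratio: 0.01            # light/heavy ratio below which: detected_below_loq
noise_floor_area: 200.0    # integrated area at/below which: not_detected
reference_symbol: IC       # relative-mode reference peptide
reference_scale: 100.0     # value the reference is normalized to
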