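power_W,time_min,solvent_parts,tpc
400,40,60,46.04
400,30,80,46.16
400,20,60,42.85
400,40,40,44.18
400,30,40,37.99
400,20,40,35.54
400,30,60,58.435
400,20,80,56.75
400,40,80,54.14
600,20,80,50.68
600,20,40,35.95
600,20,60,40.65
600,40,40,38.47
600,40,60,48.5
600,30,40,38.07
600,40,80,47.46
600,30,60,54.51
600,30,80,51.86
800,30,60,46.9
800,30,80,41.6
800,40,40,46.29
800,20,80,57.32
800,30,40,44.34
800,40,80,59.56
800,20,40,37.17
800,20,60,47.88
800,40,60,49.36
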