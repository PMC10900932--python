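site,campbell_fraction,campbell_cv,cristy_25y,cristy_40y,assumed_cv
Head,0.062,0.37,0.085,0.084,0.46
Scapulae+ribs+clavicles,0.153,0.17,0.189,0.197,0.27
Sternum,0.018,0.39,0.03,0.031,0.57
Cervical spine,0.035,0.29,0.037,0.039,0.30
Thoracic spine,0.175,0.14,0.153,0.161,0.18
Lumbar spine,0.155,0.16,0.117,0.123,0.33
Sacrum,0.074,0.24,0.094,0.099,0.34
Femora upper half,0.059,0.42,0.074,0.067,0.46
Humeri upper half,0.036,0.53,0.025,0.023,0.73
Pelvic bones,0.232,0.13,0.195,0.175,0.29
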