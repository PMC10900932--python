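site,n_segments
Skull,1
Cervical vertebra,3
Thoracic vertebra,5
Lumbar vertebra,5
Sternum,2
Pelvic bones,8
Sacrum,10
Proximal femora,2
Proximal humeri,1
Scapulae,3
Clavicles,3
Ribs,4
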