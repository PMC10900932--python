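n,shape,dims,coverage,rho_bone_min,rho_bone_max,tb_th,tb_sp,bvtv,ct_th,v_tbv,v_bmv,v_cbv
1,elliptic_cylinder,0.38;0.38;0.89,lateral,1.65,1.9,0.012,0.0248,0.22,0.024,0.017,0.060,0.024
2,ellipsoid,0.78;0.78;1.22,all,1.65,1.9,0.012,0.0248,0.22,0.024,0.073,0.256,0.060
3,elliptic_cylinder,0.6;0.6;3.0,lateral,1.65,1.9,0.01,0.036,0.28,0.13,0.076,0.196,0.577
4,deformed_cylinder,1.72;0.6;0.6;0.6;1.34,lateral,1.65,1.9,0.01,0.036,0.28,0.032,0.171,0.445,0.115
5,elliptic_cylinder,1.12;1.12;3.0,lateral,1.65,1.9,0.016,0.0538,0.22,0.23,0.226,0.804,1.929
6,elliptic_cylinder,0.91;0.91;3.0,lateral,1.66,1.9,0.0174,0.058,0.22,0.16,0.184,0.640,1.130
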