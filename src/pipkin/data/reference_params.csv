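flux_id,kind,gamma,f,enzyme_id,enzyme_activity
v0->3,phosphorylation,1.887205940573e+11,1.122610952223e+00,PI3KIII,1.000000000000e-15
v0->4,phosphorylation,1.119182661690e+10,1.505514637729e+00,PI4K,1.000000000000e-15
v0->5,phosphorylation,2.469739921721e+07,1.147150192365e+00,PIKfyve,1.000000000000e-15
v0->45,phosphorylation,2.725823138053e+17,5.000994744882e-02,PI4K_PIP5KI_DVL,1.000000000000e-15
v3->34,phosphorylation,2.499990605687e+09,2.182862049571e+00,PIP5KII,1.000000000000e-15
v3->35,phosphorylation,1.249818033715e+14,1.180599765386e+00,PIKfyve,1.000000000000e-15
v4->34,phosphorylation,6.001771487582e+09,2.070622575009e+00,PI3KII,1.000000000000e-15
v4->45,phosphorylation,1.815956833405e+17,5.000000007970e-02,PIP5KI,1.000000000000e-15
v5->45,phosphorylation,2.320264520777e+14,1.202603524624e+00,PIP5KII,1.000000000000e-15
v45->345,phosphorylation,5.379474864058e+14,7.672746808888e-01,PI3KI,6.100000000000e-16
v3->0,hydrolysis,2.432689947206e+14,4.964521396016e-01,MTMR,1.000000000000e-15
v4->0,hydrolysis,8.297556894825e+08,2.267873229240e+00,SAC1,1.000000000000e-15
v34->3,hydrolysis,6.541599377149e+14,5.081516589920e-01,INPP4,1.000000000000e-15
v34->4,hydrolysis,1.798958730203e+13,2.499997903929e+00,PTEN,2.300000000000e-15
v35->3,hydrolysis,3.486126876696e+10,2.499978484217e+00,SAC3,1.000000000000e-15
v35->5,hydrolysis,1.876983452361e+16,5.223080821211e-01,MTMR,1.000000000000e-15
v45->0,hydrolysis,2.571245714109e+14,6.757231496783e-01,SYNJ,1.000000000000e-15
v45->4,hydrolysis,1.411935340057e+14,8.915954647023e-01,SIOSS,1.000000000000e-15
v45->5,hydrolysis,7.044647896670e+06,1.183258384824e+00,SYNJ_TMEM55,1.000000000000e-15
v345->34,hydrolysis,1.000000000000e+11,9.982000000000e-01,SHIP,1.000000000000e-15
v345->45,hydrolysis,6.192234467275e+16,1.220128598568e+00,PTEN,2.300000000000e-15
v->0,influx,8.614402737533e+03,,,
v->4,influx,3.744815443881e+02,,,
v->3,influx,1.503139402833e+01,,,
v->,efflux,4.500000000000e-02,1.000000000000e+00,,
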