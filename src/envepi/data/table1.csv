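variant,mut_a,mut_b,background_mut,background_state,env,category,sign_changer
LacI_inv1,S97P,R207L,T258A,absent,Env_0,M,
LacI_inv1,S97P,R207L,T258A,absent,Env_1,M,
LacI_inv1,S97P,T258A,R207L,absent,Env_0,S,T258A
LacI_inv1,S97P,T258A,R207L,absent,Env_1,M,
LacI_inv1,R207L,T258A,S97P,present,Env_0,S,R207L
LacI_inv1,R207L,T258A,S97P,present,Env_1,M,
LacI_inv1,S97P,T258A,R207L,present,Env_0,S,T258A
LacI_inv1,S97P,T258A,R207L,present,Env_1,M,
LacI_inv1,R207L,T258A,S97P,absent,Env_0,M,
LacI_inv1,R207L,T258A,S97P,absent,Env_1,M,
LacI_inv1,S97P,R207L,T258A,present,Env_0,M,
LacI_inv1,S97P,R207L,T258A,present,Env_1,M,
LacI_inv2,S97P,L307H,L349P,absent,Env_0,S,L307H
LacI_inv2,S97P,L307H,L349P,absent,Env_1,M,
LacI_inv2,S97P,L349P,L307H,absent,Env_0,S,L349P
LacI_inv2,S97P,L349P,L307H,absent,Env_1,M,
LacI_inv2,L307H,L349P,S97P,present,Env_0,S,L349P
LacI_inv2,L307H,L349P,S97P,present,Env_1,R,
LacI_inv2,S97P,L349P,L307H,present,Env_0,M,
LacI_inv2,S97P,L349P,L307H,present,Env_1,S,L349P
LacI_inv2,L307H,L349P,S97P,absent,Env_0,M,
LacI_inv2,L307H,L349P,S97P,absent,Env_1,M,
LacI_inv2,S97P,L307H,L349P,present,Env_0,S,L307H
LacI_inv2,S97P,L307H,L349P,present,Env_1,S,L307H
LacI_inv3,S97P,G315D,P339H,absent,Env_0,S,G315D
LacI_inv3,S97P,G315D,P339H,absent,Env_1,S,G315D
LacI_inv3,S97P,P339H,G315D,absent,Env_0,M,
LacI_inv3,S97P,P339H,G315D,absent,Env_1,M,
LacI_inv3,G315D,P339H,S97P,present,Env_0,S,P339H
LacI_inv3,G315D,P339H,S97P,present,Env_1,M,
LacI_inv3,S97P,P339H,G315D,present,Env_0,S,P339H
LacI_inv3,S97P,P339H,G315D,present,Env_1,M,
LacI_inv3,G315D,P339H,S97P,absent,Env_0,M,
LacI_inv3,G315D,P339H,S97P,absent,Env_1,M,
LacI_inv3,S97P,G315D,P339H,present,Env_0,S,G315D
LacI_inv3,S97P,G315D,P339H,present,Env_1,S,G315D
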