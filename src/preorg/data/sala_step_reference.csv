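# Published reference values (kcal/mol) for the third-step barrier
# (TS3 relative to E-I2) and the E-PC stabilization (E-PC relative to
# E-I2) in each subunit and electrostatic variant. The Velec(D17&WAT)
# variant (atrophy + Asp17 + water charges restored) has no cumulative
# source profile in this package, so those cells cannot be regenerated
# by arithmetic and are reference-only.
# Transcribed published values; not computed here.
subunit,variant,point,value_kcal_mol
beta5,Velec(ON),TS3,8.9
beta5,Velec(ON),E-PC,-48.6
beta5,Velec(OFF),TS3,27.4
beta5,Velec(OFF),E-PC,16.4
beta5,Velec(D17),TS3,16.0
beta5,Velec(D17),E-PC,-1.6
beta5,Velec(D17&WAT),TS3,10.1
beta5,Velec(D17&WAT),E-PC,-35.1
beta2,Velec(ON),TS3,11.3
beta2,Velec(ON),E-PC,-44.7
beta2,Velec(OFF),TS3,27.4
beta2,Velec(OFF),E-PC,4.4
beta2,Velec(D17),TS3,16.5
beta2,Velec(D17),E-PC,-10.5
beta2,Velec(D17&WAT),TS3,13.1
beta2,Velec(D17&WAT),E-PC,-30.6
beta1,Velec(ON),TS3,13.0
beta1,Velec(ON),E-PC,-49.0
beta1,Velec(OFF),TS3,23.4
beta1,Velec(OFF),E-PC,-3.0
beta1,Velec(D17),TS3,17.0
beta1,Velec(D17),E-PC,-21.0
beta1,Velec(D17&WAT),TS3,8.1
beta1,Velec(D17&WAT),E-PC,-73.5
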