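# Stationary-point Gibbs free-energy profiles (kcal/mol, cumulative,
# relative to the Michaelis complex E:SalA) for the inactivation of the
# 20S proteasome catalytic subunits by Salinosporamide A, under three
# electrostatic conditions: Velec(ON) (unperturbed), Velec(OFF) (full
# charge atrophy: only Thr1, Lys33 and the substrate charged) and
# Velec(D17) (atrophy with Asp17 charges restored).
# Transcribed published QM/MM (M06-2X:AM1/MM) values; not computed here.
subunit,variant,label,kind,G_kcal_mol
beta5,Velec(ON),E:SalA,min,0.0
beta5,Velec(ON),TS1,ts,20.4
beta5,Velec(ON),E-I1,min,6.6
beta5,Velec(ON),TS2,ts,13.8
beta5,Velec(ON),E-I2,min,9.1
beta5,Velec(ON),TS3,ts,18.8
beta5,Velec(ON),E-PC,min,-39.5
beta5,Velec(OFF),E:SalA,min,0.0
beta5,Velec(OFF),TS1,ts,32.4
beta5,Velec(OFF),E-I1,min,32.0
beta5,Velec(OFF),TS2,ts,42.0
beta5,Velec(OFF),E-I2,min,39.1
beta5,Velec(OFF),TS3,ts,66.5
beta5,Velec(OFF),E-PC,min,55.5
beta5,Velec(D17),E:SalA,min,0.0
beta5,Velec(D17),TS1,ts,18.5
beta5,Velec(D17),E-I1,min,8.5
beta5,Velec(D17),TS2,ts,14.6
beta5,Velec(D17),E-I2,min,11.5
beta5,Velec(D17),TS3,ts,27.5
beta5,Velec(D17),E-PC,min,9.9
beta2,Velec(ON),E:SalA,min,0.0
beta2,Velec(ON),TS1,ts,20.5
beta2,Velec(ON),E-I1,min,11.8
beta2,Velec(ON),TS2,ts,18.8
beta2,Velec(ON),E-I2,min,8.7
beta2,Velec(ON),TS3,ts,20.0
beta2,Velec(ON),E-PC,min,-36.0
beta2,Velec(OFF),E:SalA,min,0.0
beta2,Velec(OFF),TS1,ts,34.2
beta2,Velec(OFF),E-I1,min,33.8
beta2,Velec(OFF),TS2,ts,45.8
beta2,Velec(OFF),E-I2,min,42.6
beta2,Velec(OFF),TS3,ts,70.0
beta2,Velec(OFF),E-PC,min,47.0
beta2,Velec(D17),E:SalA,min,0.0
beta2,Velec(D17),TS1,ts,19.6
beta2,Velec(D17),E-I1,min,8.0
beta2,Velec(D17),TS2,ts,16.4
beta2,Velec(D17),E-I2,min,13.0
beta2,Velec(D17),TS3,ts,29.5
beta2,Velec(D17),E-PC,min,2.5
beta1,Velec(ON),E:SalA,min,0.0
beta1,Velec(ON),TS1,ts,19.4
beta1,Velec(ON),E-I1,min,1.2
beta1,Velec(ON),TS2,ts,12.7
beta1,Velec(ON),E-I2,min,9.8
beta1,Velec(ON),TS3,ts,22.8
beta1,Velec(ON),E-PC,min,-39.2
beta1,Velec(OFF),E:SalA,min,0.0
beta1,Velec(OFF),TS1,ts,31.5
beta1,Velec(OFF),E-I1,min,30.5
beta1,Velec(OFF),TS2,ts,40.8
beta1,Velec(OFF),E-I2,min,38.6
beta1,Velec(OFF),TS3,ts,62.0
beta1,Velec(OFF),E-PC,min,35.6
beta1,Velec(D17),E:SalA,min,0.0
beta1,Velec(D17),TS1,ts,17.3
beta1,Velec(D17),E-I1,min,6.3
beta1,Velec(D17),TS2,ts,15.1
beta1,Velec(D17),E-I2,min,11.9
beta1,Velec(D17),TS3,ts,28.9
beta1,Velec(D17),E-PC,min,-9.1
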