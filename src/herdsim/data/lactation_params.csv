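breed,parity_class,form,a,b,c,d
Holstein,1,WOOD,16.5,0.22,0.0024,0.0
Holstein,2,WOOD,21.0,0.24,0.003,0.0
Holstein,3+,WOOD,23.0,0.25,0.0033,0.0
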