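series,t,T,dnu
upper,0,15,0
upper,1000,30,300
upper,1500,45,250
upper,2000,40,300
upper,2500,15,-300
upper,4000,45,300
upper,4500,30,0
upper,5000,15,-300
upper,5500,15,-100
upper,6000,15,150
lower,0,15,0
lower,1500,37,700
lower,2000,25,300
lower,2500,15,100
lower,3500,37,700
lower,4000,25,300
lower,4500,15,100
lower,6000,37,700
lower,6500,25,300
lower,7000,15,100
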