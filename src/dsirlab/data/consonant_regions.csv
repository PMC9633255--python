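label,duration_ms,target_f_lo_khz,target_f_hi_khz,conflicting_f_lo_khz,conflicting_f_hi_khz,target_t_lo_ms,target_t_hi_ms
pa,240,0.3,7.4,1.4,2.0,32,62
ba,331,0.3,4.5,0.6,2.2,7,22
ta,338,3.0,7.4,1.6,2.8,42,62
da,240,4.0,7.8,1.4,2.8,38,48
ka,447,1.4,2.0,5.0,7.8,30,50
ga,348,1.4,2.0,3.9,5.0,10,30
ma,350,0.5,1.3,1.2,1.9,25,55
na,400,1.5,2.2,0.4,0.9,77,127
fa,548,0.6,2.2,3.0,7.8,141,166
va,349,0.6,1.4,1.4,4.4,16,46
sa,501,3.9,7.8,5.4,7.8,80,115
za,501,3.6,7.8,3.5,5.4,90,120
sha,549,2.0,3.7,4.0,7.8,40,160
zha,550,1.9,3.7,5.4,7.8,15,115
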