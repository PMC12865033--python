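dimension,level,decrement
mo,2,0.0492
mo,3,0.1230
mo,4,0.2542
mo,5,0.4100
sc,2,0.0456
sc,3,0.1140
sc,4,0.2356
sc,5,0.3800
ua,2,0.0396
ua,3,0.0990
ua,4,0.2046
ua,5,0.3300
pd,2,0.0480
pd,3,0.1200
pd,4,0.2480
pd,5,0.4000
ad,2,0.0394
ad,3,0.0984
ad,4,0.2034
ad,5,0.3280
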