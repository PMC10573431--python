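site,distance,delta_g
His67,3.7,-4.9
Tyr138,not found,
Tyr140,4.0,-5.4
His146,3.7,-5.6
Lys199,3.0,-5.9
His242,3.5,-7.5
His247,3.7,-4.2
His338,3.6,-5.8
Lys351,3.8,-6.9
Tyr411,3.7,-6.8
Lys414,3.3,-7.2
Lys432,not found,
Lys525,3.4,-5.3
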