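compound_id,calculated,experimental
SM25,1.89,2.67
SM26,-0.21,1.04
SM27,1.76,1.56
SM28,0.83,1.18
SM29,1.24,1.61
SM30,3.54,2.76
SM31,1.62,1.96
SM32,1.64,2.44
SM33,4.29,2.96
SM34,2.40,2.83
SM35,0.77,0.88
SM36,3.75,0.76
SM37,1.88,1.45
SM38,0.48,1.03
SM39,2.48,1.89
SM40,1.43,1.83
SM41,0.88,0.58
SM42,3.75,1.76
SM43,1.85,0.85
SM44,-0.16,1.16
SM45,2.04,2.55
SM46,0.95,1.72
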