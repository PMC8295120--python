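compound_id,calculated,experimental,calculated_corrected
SM25,7.24,4.49,3.30
SM26,4.52,4.91,
SM27,12.34,10.45,
SM28,16.12,> 12.00,
SM29,11.51,10.05,
SM30,11.00,10.29,
SM31,10.84,11.02,
SM32,11.95,10.45,
SM33,10.69,> 12.00,
SM34,10.64,11.93,
SM35,10.28,9.87,
SM36,9.20,9.8,
SM37,8.11,10.33,
SM38,9.82,9.44,
SM39,8.85,10.22,
SM40,8.26,9.58,
SM41,5.13,5.22,
SM42,4.86,6.62,
SM43,4.43,5.62,
SM44,7.09,6.34,
SM45,7.37,5.93,
SM46,5.56,6.42,
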