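>python_Kp1_10
YNLNSFGLRY
>python_Kp2_10
FNFNSFGLRF
>turtle_Kp1_10
YNWNSFGLRY
>turtle_Kp2_10
FNFNPFGLRF
>mallard_Kp10_like
FIFNPFGLGF
>zebrafinch_Kp10_like
FKVNLLGLGF
>pigeon_Kp10_like
FNVNPLGVGF
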