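>ref_IIa_1
LQSCPDQPWRKYGQKRDGQTCGWGTCSQIKWAYENPLAIDDKKETWVRHMH
>ref_IIa_2
LQSCPDQPWRKYGQKRDGQTCGEGTCSQIKWAYENPLAIDDKKETWVRHMH
>ref_IIb_1
SFVLFASAWRKYGQKSGELDCWWKSCKYFFYASSRGVKWWYGFAGTFVHTH
>ref_IIb_2
SFVLFASAWRKYGQKSGEKDCWWKSCKYFFYASSRGVKWWYGFAGTFVHTH
>ref_IIc_1
CWNDVKEEWRKYGQKNVVYPCFLLICLVQAVDEIPEKSMNDEWVVQDVHTH
>ref_IIc_2
CWNDVWEEWRKYGQKNVVYPCFLLICLVQAVDEIPEWSMNDEWVVQDVHTH
>ref_IId_1
MYLRIANFWRKYGQKLEQPACVYDYCGGMLWMQKLPLVKLMMWTYPIEHYH
>ref_IId_2
MYLRIANFWRKYGQKLEQPACVYDYCGGMLWMKKLALVKLMMWTYPIEHYH
>ref_IIe_1
KLHYVADTWRKYGQKARMDPCIWQYCVSRMWLVGAQPNNTQYMLKKMGHPH
>ref_IIe_2
KLHYVADTWRKYGQKARMDPCIWQYCVSRMALVGAQPNNTQYMLKKMGHPH
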