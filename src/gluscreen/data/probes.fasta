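>S1 glutamate-binding S1 probe segment (57 aa)
NSEYVRQNSISAGITAVAEGELDILIGPISVTPERAAIEGITFTQPYFSSGIGLLIP
>S2 glutamate-binding S2 probe segment (69 aa)
EAVMFDRPALIYYTRQNPNLNLEVTEIRVSLEPYGFVLKENSPLQKTINVEMLNLLYSRVIAEFTERWL
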