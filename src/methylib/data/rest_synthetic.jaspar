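>SYN0001.1 REST_synthetic
A [  20  60   8  20  12   8  20  60   8  20  60   8  20  60   8  20  12  60  20  60   8  20  12   8  20  60   8  20  12 ]
C [  12  12  60  12   8  20  60  12  20  60  12  60  60  12  20  12   8   8  60  12  20  60   8  60  60  12  60  12   8 ]
G [  60   8  20   8  20  12  12   8  60  12   8  20  12   8  12  60  60  20  12   8  60  12  60  20  12   8  20   8  60 ]
T [   8  20  12  60  60  60   8  20  12   8  20  12   8  20  60   8  20  12   8  20  12   8  20  12   8  20  12  60  20 ]
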