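<topology> ::= <input> <conv-layers> <dense-layers> <learning>
<input> ::= batch <batch-size> window <window-size> step <window-step>
<batch-size> ::= 25 | 50 | 100
<window-size> ::= 8 | 16 | 24 | 32
<window-step> ::= 1 | 2 | 4
<conv-layers> ::= <conv> | <conv> <conv> | <conv> <conv> <conv> | <conv> <conv> <conv> <conv> | <conv> <conv> <conv> <conv> <conv>
<conv> ::= conv <kernels> <kernel-size> <pooling> <activation>
<kernels> ::= 8 | 16 | 32 | 64 | 128 | 256
<kernel-size> ::= 2 | 3 | 4
<pooling> ::= 1 | 2 | 3
<activation> ::= linear | relu
<dense-layers> ::= <dense> | <dense> <dense> | <dense> <dense> <dense>
<dense> ::= dense <dense-type> <units> <dropout> <activation> <regularizer>
<dense-type> ::= feedforward | lstm | gru
<units> ::= 128 | 256 | 512 | 1024
<dropout> ::= 0.0 | 0.25 | 0.5
<regularizer> ::= none | l1 | l2
<learning> ::= optimizer <optimizer> rate <learning-rate>
<optimizer> ::= sgd | adagrad | adadelta | rmsprop | adam | adamax
<learning-rate> ::= 0.001 | 0.0005 | 0.0001
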