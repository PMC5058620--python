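>H synthetic heavy-chain consensus (sequential numbering 1-125)
QVQLVQSGAEVKKPGASVKVSSCKASGYTFTSYGMHVAWVRQAPGQGLEWMGRITISAYSGITYASVKGRFTISRDTSKSTAYLQMSSLRAEDTAVYYAVSKFCARGGYSSGWYFDVWGQGTLVT
>L synthetic light-chain consensus (sequential numbering 1-125)
DIQMTQSPSSLSASVGDRVTITCRASQSISSYLASTVAWYQQKPGKAPKLLIYAASSLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYAVQHDEKLPLTFCQQSYSTPLTWSFGFGQGTKVE
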