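>B2GPI_DI_DII mature beta-2-glycoprotein I residues 1-125 (domains I-II; UniProt P02749)
GRTCPKPDDLPFSTVVPLKTFYEPGEEITYSCKPGYVSRGGMRKFICPLTGLWPINTLKC
TPRVCPFAGILENGAVRYTTFEYPNTISFSCNTGFYLNGADSAKCTEEGKWSPELPVCAP
IICPP
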