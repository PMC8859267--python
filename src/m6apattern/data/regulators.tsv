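gene	role
CBLL1	writer
KIAA1429	writer
METTL14	writer
METTL13	writer
RBM15	writer
RBM15B	writer
WTAP	writer
FTO	eraser
ALKBH5	eraser
ALKBH3	eraser
YTHDF1	reader
YTHDF2	reader
YTHDF3	reader
YTHDC1	reader
YTHDC2	reader
LRPPRC	reader
IGF2BP2	reader
IGF2BP3	reader
HNRNPC	reader
HNRNPA2B1	reader
ELAVL1	reader
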