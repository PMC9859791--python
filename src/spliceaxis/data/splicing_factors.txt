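# synthetic placeholder panel of 69 splicing factors; replace with your own list
SRSF1
SRSF2
SRSF3
SRSF4
SRSF5
SRSF6
SRSF7
SRSF8
SRSF9
SRSF10
SRSF11
SRSF12
HNRNPA1
HNRNPA2B1
HNRNPC
HNRNPD
HNRNPF
HNRNPH1
HNRNPH3
HNRNPK
HNRNPL
HNRNPM
HNRNPU
U2AF1
U2AF2
SF1
SF3A1
SF3A2
SF3A3
SF3B1
SF3B2
SF3B3
SF3B4
RBM5
RBM10
RBM17
RBM22
RBM25
RBM39
PTBP1
PTBP2
ELAVL1
ELAVL2
CELF1
CELF2
MBNL1
MBNL2
MBNL3
QKI
FUS
TARDBP
EWSR1
TIA1
TIAL1
KHDRBS1
TRA2A
TRA2B
ESRP1
ESRP2
NOVA1
NOVA2
SRPK1
SRPK2
CLK1
DDX17
DDX39B
SNRNP70
RBFOX1
RBFOX2
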