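# organism: E_coli
# source: synthetic snapshot (hand-constructed, emulates E_coli codon preferences; NOT database data)
# fields: codon  frequency-per-1000  (count)

UUU  25.2( 10861)  UCU  11.2(  4849)  UAU  18.0(  7758)  UGU   6.8(  2909)
UUC  16.8(  7241)  UCC  11.2(  4849)  UAC  12.0(  5172)  UGC   8.2(  3556)
UUA  12.7(  5459)  UCA   8.8(  3771)  UAA  11.4(  4913)  UGA   6.3(  2730)
UUG  11.1(  4777)  UCG  11.2(  4849)  UAG   1.3(   546)  UGG  12.0(  5172)

CUU   9.5(  4094)  CCU   7.2(  3103)  CAU  13.2(  5689)  CGU  20.5(  8839)
CUC   9.5(  4094)  CCC   6.0(  2586)  CAC   8.8(  3793)  CGC  20.5(  8839)
CUA   3.2(  1365)  CCA   9.6(  4138)  CAA  14.0(  6034)  CGA   3.7(  1607)
CUG  49.1( 21155)  CCG  25.2( 10861)  CAG  26.0( 11206)  CGG   5.6(  2411)

AUU  27.5( 11852)  ACU   9.1(  3922)  AAU  21.5(  9266)  AGU  11.2(  4849)
AUC  22.0(  9482)  ACC  22.1(  9525)  AAC  21.5(  9266)  AGC  21.2(  9159)
AUA   5.5(  2370)  ACA   7.8(  3362)  AAA  45.0( 19395)  AGA   2.8(  1205)
AUG  23.0(  9913)  ACG  13.0(  5603)  AAG  15.0(  6465)  AGG   1.9(   804)

GUU  17.3(  7467)  GCU  12.2(  5280)  GAU  34.5( 14848)  GGU  22.8(  9805)
GUC  12.6(  5431)  GCC  19.2(  8297)  GAC  18.5(  7995)  GGC  26.0( 11206)
GUA  11.0(  4752)  GCA  15.8(  6788)  GAA  44.1( 19007)  GGA   6.5(  2802)
GUG  22.0(  9504)  GCG  22.8(  9805)  GAG  18.9(  8146)  GGG   9.8(  4202)
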