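# organism: S_cerevisiae
# source: synthetic snapshot (hand-constructed, emulates S_cerevisiae codon preferences; NOT database data)
# fields: codon  frequency-per-1000  (count)

UUU  25.2( 10861)  UCU  21.1(  9074)  UAU  16.5(  7111)  UGU   9.0(  3879)
UUC  16.8(  7241)  UCC  13.2(  5671)  UAC  13.5(  5818)  UGC   6.0(  2586)
UUA  23.7( 10236)  UCA  14.5(  6238)  UAA   8.9(  3822)  UGA   7.0(  3003)
UUG  33.2( 14331)  UCG   6.6(  2836)  UAG   3.2(  1365)  UGG  12.0(  5172)

CUU  11.1(  4777)  CCU  13.2(  5689)  CAU  13.2(  5689)  CGU   5.5(  2370)
CUC   4.7(  2047)  CCC   6.0(  2586)  CAC   8.8(  3793)  CGC   2.7(  1185)
CUA  12.7(  5459)  CCA  22.8(  9827)  CAA  28.0( 12068)  CGA   2.7(  1185)
CUG   9.5(  4094)  CCG   6.0(  2586)  CAG  12.0(  5172)  CGG   1.8(   790)

AUU  25.7( 11062)  ACU  18.2(  7844)  AAU  23.6( 10193)  AGU  11.8(  5104)
AUC  16.5(  7111)  ACC  11.7(  5043)  AAC  19.3(  8340)  AGC   7.9(  3403)
AUA  12.8(  5531)  ACA  15.6(  6724)  AAA  36.0( 15516)  AGA  26.6( 11457)
AUG  23.0(  9913)  ACG   6.5(  2801)  AAG  24.0( 10344)  AGG  15.6(  6716)

GUU  25.2( 10861)  GCU  29.7( 12822)  GAU  34.4( 14848)  GGU  30.9( 13307)
GUC  12.6(  5431)  GCC  15.7(  6788)  GAC  18.5(  7995)  GGC  13.0(  5603)
GUA  12.6(  5431)  GCA  17.5(  7542)  GAA  44.1( 19007)  GGA  13.0(  5603)
GUG  12.6(  5431)  GCG   7.0(  3017)  GAG  18.9(  8146)  GGG   8.1(  3502)
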