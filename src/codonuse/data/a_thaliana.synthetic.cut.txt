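# organism: A_thaliana
# source: synthetic snapshot (hand-constructed, emulates A_thaliana codon preferences; NOT database data)
# fields: codon  frequency-per-1000  (count)

UUU  23.1(  9956)  UCU  20.5(  8816)  UAU  15.0(  6465)  UGU   8.2(  3556)
UUC  18.9(  8146)  UCC  10.9(  4702)  UAC  15.0(  6465)  UGC   6.7(  2909)
UUA  13.6(  5849)  UCA  15.0(  6465)  UAA   7.0(  3003)  UGA   7.6(  3276)
UUG  22.1(  9505)  UCG   6.8(  2939)  UAG   4.4(  1911)  UGG  12.0(  5172)

CUU  23.7( 10236)  CCU  16.4(  7077)  CAU  13.2(  5689)  CGU   8.5(  3678)
CUC  15.3(  6580)  CCC   7.6(  3267)  CAC   8.8(  3793)  CGC   5.7(  2452)
CUA  10.2(  4387)  CCA  17.7(  7622)  CAA  24.0( 10344)  CGA   6.6(  2861)
CUG  10.2(  4387)  CCG   6.3(  2722)  CAG  16.0(  6896)  CGG   4.7(  2044)

AUU  24.8( 10705)  ACU  17.8(  7667)  AAU  23.6( 10193)  AGU  12.3(  5290)
AUC  17.7(  7647)  ACC  10.9(  4718)  AAC  19.3(  8340)  AGC   9.5(  4114)
AUA  12.4(  5353)  ACA  16.4(  7077)  AAA  28.6( 12314)  AGA  17.1(  7357)
AUG  23.0(  9913)  ACG   6.8(  2949)  AAG  31.4( 13546)  AGG  12.3(  5313)

GUU  24.9( 10718)  GCU  28.7( 12377)  GAU  34.4( 14848)  GGU  17.9(  7704)
GUC  11.6(  5002)  GCC  12.6(  5415)  GAC  18.5(  7995)  GGC  11.4(  4903)
GUA   9.9(  4287)  GCA  19.7(  8509)  GAA  34.6( 14934)  GGA  24.4( 10506)
GUG  16.6(  7146)  GCG   9.0(  3868)  GAG  28.3( 12219)  GGG  11.4(  4903)
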