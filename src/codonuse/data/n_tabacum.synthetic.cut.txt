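# organism: N_tabacum
# source: synthetic snapshot (hand-constructed, emulates N_tabacum codon preferences; NOT database data)
# fields: codon  frequency-per-1000  (count)

UUU  25.2( 10861)  UCU  20.8(  8979)  UAU  16.5(  7112)  UGU   9.0(  3879)
UUC  16.8(  7241)  UCC   9.7(  4190)  UAC  13.5(  5818)  UGC   6.0(  2586)
UUA  16.7(  7183)  UCA  16.7(  7183)  UAA   7.6(  3276)  UGA   7.6(  3276)
UUG  23.3( 10057)  UCG   5.6(  2394)  UAG   3.8(  1638)  UGG  12.0(  5172)

CUU  23.3( 10057)  CCU  17.7(  7622)  CAU  14.3(  6163)  CGU   7.7(  3327)
CUC  11.7(  5028)  CCC   6.3(  2722)  CAC   7.7(  3319)  CGC   4.8(  2079)
CUA  11.7(  5028)  CCA  18.9(  8166)  CAA  26.0( 11206)  CGA   6.8(  2911)
CUG   8.3(  3592)  CCG   5.1(  2178)  CAG  14.0(  6034)  CGG   3.9(  1664)

AUU  26.6( 11470)  ACU  19.2(  8257)  AAU  25.8( 11120)  AGU  13.9(  5986)
AUC  14.2(  6117)  ACC   9.6(  4129)  AAC  17.2(  7413)  AGC   8.3(  3592)
AUA  14.2(  6117)  ACA  17.8(  7667)  AAA  31.4( 13546)  AGA  19.3(  8318)
AUG  23.0(  9913)  ACG   5.5(  2359)  AAG  28.6( 12314)  AGG  12.5(  5406)

GUU  25.8( 11140)  GCU  30.5( 13151)  GAU  37.1( 15990)  GGU  19.5(  8404)
GUC   9.7(  4177)  GCC  10.8(  4642)  GAC  15.9(  6853)  GGC   9.8(  4202)
GUA  12.9(  5570)  GCA  21.5(  9283)  GAA  37.8( 16292)  GGA  26.0( 11206)
GUG  14.5(  6266)  GCG   7.2(  3094)  GAG  25.2( 10861)  GGG   9.8(  4202)
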