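>ssp-miR156-seq1 family=miR156 sorghum=sbi-MIR156a/b/c
UUGACAGAAGAGAGUGAGCAC
>ssp-miR156-seq2 family=miR156 sorghum=sbi-MIR156e
UGACAGAAGAGAGCGAGCAC
>ssp-miR160-seq1 family=miR160 sorghum=sbi-MIR160a/c/d
UGCCUGGCUCCCUGUAUGCCA
>ssp-miR160-seq2 family=miR160 sorghum=sbi-MIR160f
UGCCUGGCUCCCUGAAUGCCA
>ssp-miR160-seq3 family=miR160 sorghum=sbi-MIR160b
AGGUAGAGGAGAAGAGUG
>ssp-miR164 family=miR164 sorghum=sbi-MIR164b
UGGAGAAGCAGGGCACGUGCU
>ssp-miR166-seq1 family=miR166 sorghum=sbi-MIR166b/c/d
UCGGACCAGGCUUCAUUCCCC
>ssp-miR166-seq2 family=miR166 sorghum=sbi-MIR166f/k
UCGGACCAGGCUUCAUUCCUC
>ssp-miR166-seq3 family=miR166 sorghum=sbi-MIR166e/f/g
UCGGACCAGGCUUCAAUCCCU
>ssp-miR167b-1 family=miR167 sorghum=sbi-MIR167a
UGAAGCUGCCAGCAUGAUCU
>ssp-miR167b-2 family=miR167 sorghum=sbi-MIR167g/h
UGAAGCUGCCAGCAUGAUCUGA
>ssp-miR167b-3 family=miR167 sorghum=sbi-MIR167c
UGAAGCUGCCAGCAUGAUCUG
>ssp-miR168a family=miR168 sorghum=sbi-MIR168
UCGCUUGGUGCAGAUCGGGAC
>ssp-miR169-seq1 family=miR169 sorghum=sbi-MIR169o
GGGCAAAUCAUCCGGGCUAGC
>ssp-miR169-seq2 family=miR169 sorghum=sbi-MIR169a
CGGCAAGUUGUUCUUGGCUAC
>ssp-miR171-seq1 family=miR171 sorghum=sbi-MIR171h
UUGAGCCGCGUCAAUAUCUCC
>ssp-miR171-seq2 family=miR171 sorghum=sbi-MIR171i
UGAUUGAGCCGUGCCAAUAUC
>ssp-miR172 family=miR172 sorghum=sbi-MIR172d
AGAAUCUUGAUGAUGCUGCAU
>ssp-miR393 family=miR393 sorghum=sbi-MIR393b
CUCCAAAGGGAUCGCAUUGAU
>ssp-miR394 family=miR394 sorghum=sbi-MIR394b
UUGGCAUUCUGUCCACCUCC
>spp-miR395-seq1 family=miR395 sorghum=sbi-MIR395a-i
GUUCCCUGCAAGCACUUCACA
>spp-miR395-seq2 family=miR395 sorghum=sbi-MIR395i/j/k
UGAAGUGUUUGGGGGAACUC
>ssp-miR396 family=miR396 sorghum=sbi-MIR396b
UUCCACAGCUUUCUUGAA
>ssp-miR397 family=miR397 sorghum=sbi-MIR397
UUGACUGCAGCGUUGAUGAGC
>ssp-miR399-seq1 family=miR399 sorghum=sbi-MIR399i
UGCCAAAGGAGAGUUGCCCU
>ssp-miR399-seq2 family=miR399 sorghum=sbi-MIR399a/h/j
UGCCAAAGGAGAAUUGCCC
>ssp-miR399-seq3 family=miR399 sorghum=sbi-MIR399b
GUGCAGCUCUCCUCUGGCAUG
>ssp-miR528 family=miR528 sorghum=sbi-MIR528
UGGAAGGGGCAUGCAGAGGAG
>ssp-miR529 family=miR529 sorghum=sbi-MIR529
AGAAGAGAGAGAGUACAGCCU
>ssp-miR1432 family=miR1432 sorghum=sbi-MIR1432
UCAGGAAAGAUGACACCAA
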