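# Kyamicin core-peptide topology (type B, cinnamycin-like lantibiotic).
# Bridges are written as [Cys position, dehydrated partner]: three
# methyllanthionines (1-18, 5-11, 14-4), a lysinoalanine 6-19 and
# beta-hydroxylation of Asp15. The core sequence is validated by the
# molecular-formula identity of the mature species (C76H108N20O25S3);
# see docs/methods.md for how the sequence is constrained.
name: kyamicin
core_sequence: CASTCSFGPATFACDGSTK
dehydrations: [4, 6, 11, 18]
thioether_bridges: [[1, 18], [5, 11], [14, 4]]
lysinoalanine: [6, 19]
hydroxylations: [15]
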