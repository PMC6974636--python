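# Cinnamycin (Ro 09-0198) core-peptide topology, the founding member of
# the family. Mature formula: C89H125N25O25S3.
name: cinnamycin
core_sequence: CRQSCSFGPFTFVCDGNTK
dehydrations: [4, 6, 11, 18]
thioether_bridges: [[1, 18], [5, 11], [14, 4]]
lysinoalanine: [6, 19]
hydroxylations: [15]
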