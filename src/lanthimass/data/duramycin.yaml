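# Duramycin core-peptide topology. Same scaffold as cinnamycin with Lys2;
# ring 14-4 is a lanthionine (Ser4-derived), the other two are
# methyllanthionines. Mature formula: C89H125N23O25S3.
name: duramycin
core_sequence: CKQSCSFGPFTFVCDGNTK
dehydrations: [4, 6, 11, 18]
thioether_bridges: [[1, 18], [5, 11], [14, 4]]
lysinoalanine: [6, 19]
hydroxylations: [15]
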