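# lanthimass

Mass-spectrometric bookkeeping for cross-linked lanthipeptides — the
calculations used to confirm the structure of type B (cinnamycin-like)
lantibiotics such as kyamicin and duramycin from UPLC-MS and MALDI-TOF
data.

Lanthipeptides are ribosomally synthesized peptides whose Ser/Thr residues
are dehydrated (Ser → Dha, Thr → Dhb, −H2O each) and then cyclised by Cys
thiol addition into lanthionine/methyllanthionine thioether bridges.
Members of the cinnamycin family additionally carry a lysinoalanine
cross-link (Dha6–Lys19) and a β-hydroxylated Asp15. Because cyclisation
moves no atoms once the dehydration is counted, the whole mass model is a
small exact algebra over elemental formulas:

```
M(mature)      =  M(linear peptide) − n_dehydration · H2O + n_hydroxylation · O
M(deoxy)       =  M(mature) − O                    (hydroxylase skipped)
M(k reduced)   =  M(mature) − k·S + 2k·H           (NiCl2/NaBH4 desulfurization)
m/z([M+zH]z+)  =  (M + z·m_proton) / z
ppm            =  (observed − calculated) / calculated × 1e6
```

On top of that kernel the package provides:

* **Structure model** — core sequence + bridge topology as data (YAML
  configs for kyamicin, cinnamycin and duramycin ship with the package),
  with species variants (mature / deoxy / k-fold desulfurized) and leader
  peptide removal from FASTA precursors.
* **Reduction ladders** — the [M+2H]2+ series of successive thioether
  desulfurization, spaced by (m_S − 2·m_H)/2 ≈ 14.9782.
* **y-ion fragmentation** — the singly protonated y series of the reduced
  peptide, including the lysinoalanine rearrangement observed in
  MALDI-TOF LIFT spectra (severed bridge → glycine at the Dha position
  and N=CH2 at the lysine side chain, an atom-conserving split).
* **Annotation** — ppm-tolerance screening of observed peak lists for
  predicted species, the in-silico analogue of extracted-ion-chromatogram
  screening.
* **Synthetic data** — seeded peak-list simulation (Gaussian ppm error,
  log-normal intensities, uniform decoys) with ground truth, for
  end-to-end validation without instrument data.

## Worked example

```bash
$ lanthimass predict kyamicin --deoxy
      species         formula  charge  calc_mz  eic_mz
     kyamicin C76H108N20O25S3       2 899.3551  899.36
deoxykyamicin C76H108N20O24S3       2 891.3577  891.36
```

The mature formula C76H108N20O25S3 is derived from the 19-residue core by
−4·H2O (Thr4, Ser6, Thr11, Thr18 dehydrations) and +O (Asp15 hydroxyl);
899.3551 is the doubly protonated monoisotopic m/z, and 899.36 the 2-dp
window used for extracted-ion chromatograms. `deoxykyamicin` is the
species produced when β-hydroxylation is incomplete, half an oxygen lower
in m/z at z = 2.

```bash
$ lanthimass reduce kyamicin
                         species  k_reduced         formula  charge  calc_mz
                        kyamicin          0 C76H108N20O25S3       2 899.3551
partially reduced kyamicin (k=1)          1 C76H110N20O25S2       2 884.3769
partially reduced kyamicin (k=2)          2  C76H112N20O25S       2 869.3987
                reduced kyamicin          3   C76H114N20O25       2 854.4205
```

Each desulfurized bridge removes one S and adds two H, stepping the z = 2
ion down by 14.9782. The y-ion ladder of the fully reduced peptide
(`lanthimass fragment kyamicin`) starts at the rearranged C-terminal
lysine:

```
series  n  span       formula   calc_mz  rearranged
     y  1 19-19     C7H14N2O2  159.1128        True
     y  2 18-19    C11H21N3O3  244.1656        True
```

`lanthimass simulate … --out peaks.csv` writes a synthetic peak list plus
ground truth, and `lanthimass annotate … --peaks peaks.csv` screens any
peak CSV for the predicted species, reporting the nearest peak, signed
ppm error and a detected flag per species and charge.

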