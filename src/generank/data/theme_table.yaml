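# Converging functional themes identified for module M9.2 by four chat
# models and two enrichment tools, with member genes as printed.  Note the
# Claude interferon-response row lists IFITL1 while the module fixture
# (following the module table) spells it IFIT1L; the discrepancy is
# reproduced, not resolved.
assignments:
  - source: GPT3.5
    theme: Hemoglobin synthesis and red blood cell function
    genes: [ALAS2, CA1, EPB42, FECH, GYPB, GYPE, SLC4A1]
  - source: GPT3.5
    theme: Enzymes and metabolic processes
    genes: [BPGM, FECH, GMPR]
  - source: GPT3.5
    theme: Cytoskeletal proteins
    genes: [KRT1, TUBB2A]
  - source: GPT-4
    theme: Erythrocyte development and function
    genes: [ALAS2, BPGM, EPB42, GYPB, GYPE, SLC4A1, XK, FECH]
  - source: GPT-4
    theme: Cytoskeleton and cellular structure
    genes: [TNS1, TMOD1, TUBB2A]
  - source: GPT-4
    theme: Ubiquitin–proteasome system
    genes: [MARCH8, TRIM10]
  - source: Claude
    theme: Erythrocyte biology or iron/heme metabolism
    genes: [ALAS2, FECH, SLC4A1]
  - source: Claude
    theme: Cytoskeletal or cytoskeleton-associated genes
    genes: [EPB42, KRT1, TMOD1, TNS1, TUBB2A]
  - source: Claude
    theme: Protein binding, degradation or trafficking
    genes: [MARCH8, TRIM10]
  - source: Claude
    theme: Interferon response
    genes: [IFITL1, SELENBP1]
  - source: Claude
    theme: phospholipid metabolism or vesicle trafficking
    genes: [OSBP2, PLEK2]
  - source: Claude
    theme: GPCR biology
    genes: [GPR146, SNCA]
  - source: Bard
    theme: Production of Heme
    genes: [ALAS2, FECH]
  - source: Bard
    theme: Glutathione synthesis
    genes: [BPGM, GYPB]
  - source: Bard
    theme: Cell signaling
    genes: [GPR146, OR2W3]
  - source: Bard
    theme: Solute carrier genes
    genes: [SLC14A1, SLC4A1]
  - source: DAVID
    theme: Blood group antigen
    genes: [XK, GYPB, SLC14A1, SLC4A1]
  - source: DAVID
    theme: Erythrocyte development and differentiation
    genes: [ALAS2, BPGM, SLC4A1]
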