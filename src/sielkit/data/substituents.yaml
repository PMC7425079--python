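# Per-substituent SIEL contributions on the tris-bipyridine ruthenium
# reference scaffold (one substituent at the 4-position of one bpy ligand),
# relaxed lowest triplet charge-transfer state.  Only the values reported in
# the primary literature source's main text are bundled; supply a fuller
# table with SubstituentTable.from_yaml for other groups.
# siel_singlet is null where no singlet value is printed.
substituents:
  CH3:
    siel_singlet: null
    siel_triplet: 0.26
  COOH:
    siel_singlet: null
    siel_triplet: -0.71
  NHCOCH3:
    siel_singlet: null
    siel_triplet: 0.41
  CONHCH3:
    siel_singlet: null
    siel_triplet: -0.69
  CH2SCH3:
    siel_singlet: null
    siel_triplet: 0.28
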