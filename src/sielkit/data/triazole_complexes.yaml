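# Literature-reported lowest-triplet excited-electron populations (percent)
# for four triazole-linked tris-bipyridine ruthenium complexes, resolved over
# five fragments (metal, the substituted bpy1, the triazole linker carrying
# R1, and the trans/cis bpy units).  The metal population is 0% in all four.
# reported_siel is the published SIEL of bpy1 computed with the triazole
# merged into bpy1 (three ligand fragments).
fragments: [Ru, bpy1, triazole, bpy2, bpy3]
roles: [metal, ligand, ligand, ligand, ligand]
complexes:
  8a:
    r1: Me
    populations: {Ru: 0, triazole: 4, bpy1: 4, bpy2: 79, bpy3: 13}
    reported_siel: 0.345
  9a:
    r1: Me
    populations: {Ru: 0, triazole: 3, bpy1: 75, bpy2: 11, bpy3: 11}
    reported_siel: -0.656
  8b:
    r1: Ph
    populations: {Ru: 0, triazole: 13, bpy1: 17, bpy2: 16, bpy3: 54}
    reported_siel: 0.039
  9b:
    r1: Ph
    populations: {Ru: 0, triazole: 15, bpy1: 54, bpy2: 14, bpy3: 17}
    reported_siel: -0.497
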