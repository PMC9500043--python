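# Default VOI specification for the 27-region PET-CT template.
# 12 bilateral entries (split left/right at the ML midline) + 3 central
# entries.  Each VOI is the union of the listed Allen ontology subtrees
# ("acronyms" name the subtree roots; every descendant is included).
# Grouping choices that the region names leave open:
#   - Hindbrain = pons + medulla (P, MY)
#   - Hippocampal region = HIP (not the wider hippocampal formation HPF)
# Edit or replace this file to regroup.
- {name: Anterior cingulate area, abbreviation: ACA, laterality: bilateral, acronyms: [ACA]}
- {name: Auditory areas, abbreviation: AUD, laterality: bilateral, acronyms: [AUD]}
- {name: Cerebellum, abbreviation: CB, laterality: central, acronyms: [CB]}
- {name: Hindbrain, abbreviation: HB, laterality: central, acronyms: [P, MY]}
- {name: Hippocampal region, abbreviation: HIP, laterality: bilateral, acronyms: [HIP]}
- {name: Hypothalamus, abbreviation: HY, laterality: bilateral, acronyms: [HY]}
- {name: Midbrain, abbreviation: MB, laterality: central, acronyms: [MB]}
- {name: Olfactory areas, abbreviation: OLF, laterality: bilateral, acronyms: [OLF]}
- {name: Orbital areas, abbreviation: ORB, laterality: bilateral, acronyms: [ORB]}
- {name: Somatomotor areas, abbreviation: MO, laterality: bilateral, acronyms: [MO]}
- {name: Somatosensory areas, abbreviation: SS, laterality: bilateral, acronyms: [SS]}
- {name: Striatum dorsal, abbreviation: STRd, laterality: bilateral, acronyms: [STRd]}
- {name: Striatum ventral, abbreviation: STRv, laterality: bilateral, acronyms: [STRv]}
- {name: Thalamus, abbreviation: TH, laterality: bilateral, acronyms: [TH]}
- {name: Visual areas, abbreviation: VIS, laterality: bilateral, acronyms: [VIS]}
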