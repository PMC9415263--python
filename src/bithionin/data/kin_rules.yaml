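# Maturation rule table for the kin (beta-bithionin) pathway.
#
# Positional roles may be given explicitly (1-based core positions) or left
# as "auto", in which case they are derived from the precursor's signature
# motif anchors S-[ST]-X-X-C-X{g}-T-X{4}-C:
#   aaa_site      auto -> the first S anchor (Ser-7 in KinA); its elimination
#                 rearranges to the beta-enamino acid Aaa (methyl-Aaa if Thr)
#   retained_ser  auto -> Ser strictly between the Thr acceptor anchor and the
#                 C-terminal Cys anchor (Ser-25 in KinA) is never dehydrated
#   reduce_sites  auto -> Ser-derived Dha strictly between the thiol Cys and
#                 the Thr acceptor anchors (13/16/18 in KinA); KinJ substrate
#   phospho_start auto -> first dehydratable position (Thr-2 in KinA)
#   crosslink     auto -> [thiol Cys, Thr acceptor, C-terminal Cys] anchors
#                 ([11, 22, 27] in KinA): the MAbi bis-thioether connectivity
name: kin
anchors: auto
aaa_site: auto
retained_ser: auto
reduce_sites: auto
phospho_start: auto
crosslink: auto
# Enzyme gating: elimination (KinC) needs prior phosphorylation (KinD);
# decarboxylation + cyclisation need the KinH/KinI pair acting on the fully
# dehydrated substrate; KinJ reduction needs dehydration; N,N-dimethylation
# (KinO) needs a free N-terminus, i.e. prior leader proteolysis (KinE/F).
requires:
  C: [D]
  J: [C, D]
  O: [EF]
decarboxylation_requires: [C, D, H, I]
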