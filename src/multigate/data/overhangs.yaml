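# Fusion-site (4-nt overhang) tables for the toolkit grammar.
#
# part_types: the published YTK Level-1 (BsaI) junction standard -- each
# Level-0 part type spans upstream->downstream fusion sites, and subtypes
# (3a/3b, 4a/4b) partition their parent's interval.
#
# level2_connectors: BsmBI overhangs for multigene-assembly connector
# positions 1..10 plus the terminal connector.  The real kit's connector
# sequences live in its distribution files and are not printed in the text;
# the defaults below are a SYNTHETIC validated set (no palindromes, no
# reverse-complement pairs, all distinct) and can be replaced verbatim by a
# kit manifest.
#
# array_fusion_sites: BsaI overhangs for gRNA-tRNA array positions (head =
# backbone acceptor upstream of fragment 1, tail = backbone acceptor after
# the last fragment, internal_1..internal_9 between consecutive fragments).
# Synthetic validated set, same caveat as above.
#
# marker_swap: the BbsI fusion pair shared by every selectable-marker
# cartridge and every integration-vector marker cloning site.
part_types:
  type1:  {upstream: CCCT, downstream: AACG}
  type2:  {upstream: AACG, downstream: TATG}
  type3:  {upstream: TATG, downstream: ATCC}
  type3a: {upstream: TATG, downstream: TTCT}
  type3b: {upstream: TTCT, downstream: ATCC}
  type4:  {upstream: ATCC, downstream: GCTG}
  type4a: {upstream: ATCC, downstream: TGGC}
  type4b: {upstream: TGGC, downstream: GCTG}
  type5:  {upstream: GCTG, downstream: TACA}
  type6:  {upstream: TACA, downstream: GAGT}
  type7:  {upstream: GAGT, downstream: CCGA}
  type8:  {upstream: CCGA, downstream: CCCT}
level2_connectors:
  con1: AACC
  con2: ACAG
  con3: AGGA
  con4: ATTC
  con5: CACG
  con6: CCTA
  con7: CGAA
  con8: CTAC
  con9: GACT
  con10: GAGG
  terminal: GCTT
array_fusion_sites:
  head: ACGG
  tail: TTAG
  internal_1: AAGT
  internal_2: ACCA
  internal_3: AGTG
  internal_4: CATC
  internal_5: CCAG
  internal_6: CGGA
  internal_7: CTTG
  internal_8: GAAC
  internal_9: GGCA
marker_swap:
  upstream: TAGC
  downstream: ATGG
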