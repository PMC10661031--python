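# Restriction-enzyme geometry table.
#
# Type IIS entries use REBASE-style offsets measured downstream from the 3'
# end of the recognition site on the recognition strand: GGTCTC(1/5) means
# the top strand is cut 1 nt after the site and the bottom strand 5 nt after,
# leaving a 4-nt 5' overhang.  Within-site cutters (type_iis: false) give
# offsets from the 5' start of the recognition site: NotI GC^GGCCGC cuts the
# top strand after position 2 and the bottom strand after position 6.
BsaI:
  recognition: GGTCTC
  cut_top: 1
  cut_bottom: 5
  type_iis: true
BsmBI:
  recognition: CGTCTC
  cut_top: 1
  cut_bottom: 5
  type_iis: true
BbsI:
  recognition: GAAGAC
  cut_top: 2
  cut_bottom: 6
  type_iis: true
NotI:
  recognition: GCGGCCGC
  cut_top: 2
  cut_bottom: 6
  type_iis: false
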