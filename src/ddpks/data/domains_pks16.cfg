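# Pks16 reference domain ranges (reference = Pks16 native numbering).
# Anchored boundaries: the KS/ACP interface mutation sites (86-88) lie in KS;
# the MT span and lid cover 1254-1414 and 1575-1594; the ACP carries the
# phosphopantetheinylated serine at 2543.  Remaining boundaries are curated
# defaults and editable here.
KS: 1-460
flanking: 461-545
AT: 546-925
DH: 936-1230
MT: 1254-1594
KR_s: 1640-1830
ER: 1831-2220
KR_c: 2221-2510
ACP: 2524-2585
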