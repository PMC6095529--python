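# Editable coding lexicon: free-text response -> canonical category.
# Matching is case-insensitive after whitespace normalization; strings
# missing from this mapping code to the OTHER bucket (kept verbatim).
wax: wax
candle wax: wax
aluminum foil: aluminum foil
aluminium foil: aluminum foil
tin foil: aluminum foil
gold foil: gold foil
gold leaf: gold foil
wire: wire
chicken wire: wire
wire mesh: wire
putty: putty
clay: putty
plasticine: putty
modelling clay: putty
cardboard: cardboard
carton: cardboard
paperboard: cardboard
twisted: twisted
wrung: twisted
crumpled: crumpled
scrunched: crumpled
scrunched up: crumpled
bent: bent
bent over: bent
folded: folded
folded up: folded
folded over: folded
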