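floral
fruity
sweet
spicy
dairy
cheesy
sweaty
pungent
nutty
minty
camphor
sulfurous
meaty
green
animalic
buttery
aldehydic
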