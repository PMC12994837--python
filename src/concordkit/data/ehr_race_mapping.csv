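source_code,category
hispanic,Hispanic
hispanic or latino,Hispanic
latino,Hispanic
latina,Hispanic
latinx,Hispanic
hispanic/latino,Hispanic
non-hispanic,NotHispanic
nonhispanic,NotHispanic
non hispanic,NotHispanic
not hispanic or latino,NotHispanic
not hispanic,NotHispanic
white,White
caucasian,White
european,White
black,Black
black or african american,Black
african american,Black
african-american,Black
aian,AIAN
american indian,AIAN
alaska native,AIAN
american indian or alaska native,AIAN
native american,AIAN
asian,Asian
asian indian,Asian
chinese,Asian
filipino,Asian
japanese,Asian
korean,Asian
vietnamese,Asian
nhpi,NHPI
native hawaiian,NHPI
pacific islander,NHPI
native hawaiian or other pacific islander,NHPI
other pacific islander,NHPI
guamanian or chamorro,NHPI
samoan,NHPI
multiracial,Multiracial
multi-racial,Multiracial
multiple races,Multiracial
two or more races,Multiracial
biracial,Multiracial
other,Unreported
other race,Unreported
unknown,Unreported
unavailable,Unreported
declined,Unreported
patient declined,Unreported
refused,Unreported
prefer not to answer,Unreported
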