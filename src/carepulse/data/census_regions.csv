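state,region
CT,NORTHEAST
MA,NORTHEAST
ME,NORTHEAST
NH,NORTHEAST
NJ,NORTHEAST
NY,NORTHEAST
PA,NORTHEAST
RI,NORTHEAST
VT,NORTHEAST
IA,MIDWEST
IL,MIDWEST
IN,MIDWEST
KS,MIDWEST
MI,MIDWEST
MN,MIDWEST
MO,MIDWEST
ND,MIDWEST
NE,MIDWEST
OH,MIDWEST
SD,MIDWEST
WI,MIDWEST
AL,SOUTH
AR,SOUTH
DC,SOUTH
DE,SOUTH
FL,SOUTH
GA,SOUTH
KY,SOUTH
LA,SOUTH
MD,SOUTH
MS,SOUTH
NC,SOUTH
OK,SOUTH
SC,SOUTH
TN,SOUTH
TX,SOUTH
VA,SOUTH
WV,SOUTH
AK,WEST
AZ,WEST
CA,WEST
CO,WEST
HI,WEST
ID,WEST
MT,WEST
NM,WEST
NV,WEST
OR,WEST
UT,WEST
WA,WEST
WY,WEST
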