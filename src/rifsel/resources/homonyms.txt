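# Gene surface forms that collide with common English words.
# Matching for these forms is case-SENSITIVE; everything else matches
# case-insensitively.  One surface form per line; '#' starts a comment.
WAS
CAT
SET
MET
KIT
REST
ACT
APP
ARC
ATM
BAD
CLOCK
COIL
CAST
DST
FUSE
GAS
ICE
IMPACT
LARGE
MARS
MICE
NODAL
OUT
PIGS
RAN
SHE
SOX
TANK
TUBE
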