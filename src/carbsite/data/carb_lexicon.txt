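# Carbohydrate HET-code lexicon (one 3-letter PDB chemical-component code per
# line; '#' starts a comment).  This default list is a curated stand-in built
# from common saccharide codes in the PDB chemical component dictionary; the
# exact published 101-code list it emulates is not reproduced verbatim.  Edit
# freely or pass your own file with --lexicon.  Water (HOH) is always refused
# regardless of file content.
GLC
BGC
GAL
GLA
MAN
BMA
FUC
FUL
XYS
XYP
ARA
ARB
RIB
RIP
FRU
AHR
NAG
NDG
NGA
A2G
GCS
PA1
GCU
BDP
GCD
IDS
IDR
SIA
SLB
NAN
KDO
GMH
LYX
RAM
RM4
ABE
TYV
PAR
DHA
XLS
LXC
ALL
ALT
SDY
TAL
GUP
GL0
SOE
PSE
TAG
SOR
GLO
GTR
GCV
MAV
BEM
ADA
GTK
LGU
MUB
AMU
MUR
BCD
ACX
GLP
G6P
G1P
BG6
F6P
FBP
M6P
M1P
NG6
GN1
X6X
TOA
TOC
DDA
DDL
RHA
QUI
OLI
TYE
ASO
DAN
4AM
SLE
NGC
NGE
LAT
LBT
MAL
MLT
CBI
CEL
TRE
SUC
RAF
MTT
ISO
DP5
G4D
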