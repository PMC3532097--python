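! amber98 radius subset (SIZ) - illustrative parameter subset bundled
! with nanopqr for testing; NOT the published force-field file.
! columns: atom_name [residue_name] radius_A
N    ALA   1.625
CA   ALA   1.700
C    ALA   1.700
O    ALA   1.480
CB   ALA   1.700
N    ARG   1.625
CA   ARG   1.700
C    ARG   1.700
O    ARG   1.480
CB   ARG   1.700
CG   ARG   1.700
CD   ARG   1.700
NE   ARG   1.625
CZ   ARG   1.700
NH1  ARG   1.625
NH2  ARG   1.625
N    ASN   1.625
CA   ASN   1.700
C    ASN   1.700
O    ASN   1.480
CB   ASN   1.700
CG   ASN   1.700
OD1  ASN   1.480
ND2  ASN   1.625
N    ASP   1.625
CA   ASP   1.700
C    ASP   1.700
O    ASP   1.480
CB   ASP   1.700
CG   ASP   1.700
OD1  ASP   1.480
OD2  ASP   1.480
N    CYS   1.625
CA   CYS   1.700
C    CYS   1.700
O    CYS   1.480
CB   CYS   1.700
SG   CYS   1.780
N    GLN   1.625
CA   GLN   1.700
C    GLN   1.700
O    GLN   1.480
CB   GLN   1.700
CG   GLN   1.700
CD   GLN   1.700
OE1  GLN   1.480
NE2  GLN   1.625
N    GLU   1.625
CA   GLU   1.700
C    GLU   1.700
O    GLU   1.480
CB   GLU   1.700
CG   GLU   1.700
CD   GLU   1.700
OE1  GLU   1.480
OE2  GLU   1.480
N    GLY   1.625
CA   GLY   1.700
C    GLY   1.700
O    GLY   1.480
N    HIS   1.625
CA   HIS   1.700
C    HIS   1.700
O    HIS   1.480
CB   HIS   1.700
CG   HIS   1.700
ND1  HIS   1.625
CD2  HIS   1.700
CE1  HIS   1.700
NE2  HIS   1.625
N    ILE   1.625
CA   ILE   1.700
C    ILE   1.700
O    ILE   1.480
CB   ILE   1.700
CG1  ILE   1.700
CG2  ILE   1.700
CD1  ILE   1.700
N    LEU   1.625
CA   LEU   1.700
C    LEU   1.700
O    LEU   1.480
CB   LEU   1.700
CG   LEU   1.700
CD1  LEU   1.700
CD2  LEU   1.700
N    LYS   1.625
CA   LYS   1.700
C    LYS   1.700
O    LYS   1.480
CB   LYS   1.700
CG   LYS   1.700
CD   LYS   1.700
CE   LYS   1.700
NZ   LYS   1.625
N    MET   1.625
CA   MET   1.700
C    MET   1.700
O    MET   1.480
CB   MET   1.700
CG   MET   1.700
SD   MET   1.780
CE   MET   1.700
N    PHE   1.625
CA   PHE   1.700
C    PHE   1.700
O    PHE   1.480
CB   PHE   1.700
CG   PHE   1.700
CD1  PHE   1.700
CD2  PHE   1.700
CE1  PHE   1.700
CE2  PHE   1.700
CZ   PHE   1.700
N    PRO   1.625
CA   PRO   1.700
C    PRO   1.700
O    PRO   1.480
CB   PRO   1.700
CG   PRO   1.700
CD   PRO   1.700
N    SER   1.625
CA   SER   1.700
C    SER   1.700
O    SER   1.480
CB   SER   1.700
OG   SER   1.480
N    THR   1.625
CA   THR   1.700
C    THR   1.700
O    THR   1.480
CB   THR   1.700
OG1  THR   1.480
CG2  THR   1.700
N    TRP   1.625
CA   TRP   1.700
C    TRP   1.700
O    TRP   1.480
CB   TRP   1.700
CG   TRP   1.700
CD1  TRP   1.700
CD2  TRP   1.700
NE1  TRP   1.625
CE2  TRP   1.700
CE3  TRP   1.700
CZ2  TRP   1.700
CZ3  TRP   1.700
CH2  TRP   1.700
N    TYR   1.625
CA   TYR   1.700
C    TYR   1.700
O    TYR   1.480
CB   TYR   1.700
CG   TYR   1.700
CD1  TYR   1.700
CD2  TYR   1.700
CE1  TYR   1.700
CE2  TYR   1.700
CZ   TYR   1.700
OH   TYR   1.480
N    VAL   1.625
CA   VAL   1.700
C    VAL   1.700
O    VAL   1.480
CB   VAL   1.700
CG1  VAL   1.700
CG2  VAL   1.700
C          1.700
N          1.625
O          1.480
S          1.780
H          1.000
OXT        1.480
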