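! charmm22 radius subset (SIZ) - illustrative parameter subset bundled
! with nanopqr for testing; NOT the published force-field file.
! columns: atom_name [residue_name] radius_A
N    ALA   1.550
CA   ALA   1.800
C    ALA   1.800
O    ALA   1.520
CB   ALA   1.800
N    ARG   1.550
CA   ARG   1.800
C    ARG   1.800
O    ARG   1.520
CB   ARG   1.800
CG   ARG   1.800
CD   ARG   1.800
NE   ARG   1.550
CZ   ARG   1.800
NH1  ARG   1.550
NH2  ARG   1.550
N    ASN   1.550
CA   ASN   1.800
C    ASN   1.800
O    ASN   1.520
CB   ASN   1.800
CG   ASN   1.800
OD1  ASN   1.520
ND2  ASN   1.550
N    ASP   1.550
CA   ASP   1.800
C    ASP   1.800
O    ASP   1.520
CB   ASP   1.800
CG   ASP   1.800
OD1  ASP   1.520
OD2  ASP   1.520
N    CYS   1.550
CA   CYS   1.800
C    CYS   1.800
O    CYS   1.520
CB   CYS   1.800
SG   CYS   1.800
N    GLN   1.550
CA   GLN   1.800
C    GLN   1.800
O    GLN   1.520
CB   GLN   1.800
CG   GLN   1.800
CD   GLN   1.800
OE1  GLN   1.520
NE2  GLN   1.550
N    GLU   1.550
CA   GLU   1.800
C    GLU   1.800
O    GLU   1.520
CB   GLU   1.800
CG   GLU   1.800
CD   GLU   1.800
OE1  GLU   1.520
OE2  GLU   1.520
N    GLY   1.550
CA   GLY   1.800
C    GLY   1.800
O    GLY   1.520
N    HIS   1.550
CA   HIS   1.800
C    HIS   1.800
O    HIS   1.520
CB   HIS   1.800
CG   HIS   1.800
ND1  HIS   1.550
CD2  HIS   1.800
CE1  HIS   1.800
NE2  HIS   1.550
N    ILE   1.550
CA   ILE   1.800
C    ILE   1.800
O    ILE   1.520
CB   ILE   1.800
CG1  ILE   1.800
CG2  ILE   1.800
CD1  ILE   1.800
N    LEU   1.550
CA   LEU   1.800
C    LEU   1.800
O    LEU   1.520
CB   LEU   1.800
CG   LEU   1.800
CD1  LEU   1.800
CD2  LEU   1.800
N    LYS   1.550
CA   LYS   1.800
C    LYS   1.800
O    LYS   1.520
CB   LYS   1.800
CG   LYS   1.800
CD   LYS   1.800
CE   LYS   1.800
NZ   LYS   1.550
N    MET   1.550
CA   MET   1.800
C    MET   1.800
O    MET   1.520
CB   MET   1.800
CG   MET   1.800
SD   MET   1.800
CE   MET   1.800
N    PHE   1.550
CA   PHE   1.800
C    PHE   1.800
O    PHE   1.520
CB   PHE   1.800
CG   PHE   1.800
CD1  PHE   1.800
CD2  PHE   1.800
CE1  PHE   1.800
CE2  PHE   1.800
CZ   PHE   1.800
N    PRO   1.550
CA   PRO   1.800
C    PRO   1.800
O    PRO   1.520
CB   PRO   1.800
CG   PRO   1.800
CD   PRO   1.800
N    SER   1.550
CA   SER   1.800
C    SER   1.800
O    SER   1.520
CB   SER   1.800
OG   SER   1.520
N    THR   1.550
CA   THR   1.800
C    THR   1.800
O    THR   1.520
CB   THR   1.800
OG1  THR   1.520
CG2  THR   1.800
N    TRP   1.550
CA   TRP   1.800
C    TRP   1.800
O    TRP   1.520
CB   TRP   1.800
CG   TRP   1.800
CD1  TRP   1.800
CD2  TRP   1.800
NE1  TRP   1.550
CE2  TRP   1.800
CE3  TRP   1.800
CZ2  TRP   1.800
CZ3  TRP   1.800
CH2  TRP   1.800
N    TYR   1.550
CA   TYR   1.800
C    TYR   1.800
O    TYR   1.520
CB   TYR   1.800
CG   TYR   1.800
CD1  TYR   1.800
CD2  TYR   1.800
CE1  TYR   1.800
CE2  TYR   1.800
CZ   TYR   1.800
OH   TYR   1.520
N    VAL   1.550
CA   VAL   1.800
C    VAL   1.800
O    VAL   1.520
CB   VAL   1.800
CG1  VAL   1.800
CG2  VAL   1.800
C          1.800
N          1.550
O          1.520
S          1.800
H          0.900
OXT        1.520
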