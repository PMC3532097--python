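! opls radius subset (SIZ) - illustrative parameter subset bundled
! with nanopqr for testing; NOT the published force-field file.
! columns: atom_name [residue_name] radius_A
N    ALA   1.600
CA   ALA   1.750
C    ALA   1.750
O    ALA   1.500
CB   ALA   1.750
N    ARG   1.600
CA   ARG   1.750
C    ARG   1.750
O    ARG   1.500
CB   ARG   1.750
CG   ARG   1.750
CD   ARG   1.750
NE   ARG   1.600
CZ   ARG   1.750
NH1  ARG   1.600
NH2  ARG   1.600
N    ASN   1.600
CA   ASN   1.750
C    ASN   1.750
O    ASN   1.500
CB   ASN   1.750
CG   ASN   1.750
OD1  ASN   1.500
ND2  ASN   1.600
N    ASP   1.600
CA   ASP   1.750
C    ASP   1.750
O    ASP   1.500
CB   ASP   1.750
CG   ASP   1.750
OD1  ASP   1.500
OD2  ASP   1.500
N    CYS   1.600
CA   CYS   1.750
C    CYS   1.750
O    CYS   1.500
CB   CYS   1.750
SG   CYS   1.850
N    GLN   1.600
CA   GLN   1.750
C    GLN   1.750
O    GLN   1.500
CB   GLN   1.750
CG   GLN   1.750
CD   GLN   1.750
OE1  GLN   1.500
NE2  GLN   1.600
N    GLU   1.600
CA   GLU   1.750
C    GLU   1.750
O    GLU   1.500
CB   GLU   1.750
CG   GLU   1.750
CD   GLU   1.750
OE1  GLU   1.500
OE2  GLU   1.500
N    GLY   1.600
CA   GLY   1.750
C    GLY   1.750
O    GLY   1.500
N    HIS   1.600
CA   HIS   1.750
C    HIS   1.750
O    HIS   1.500
CB   HIS   1.750
CG   HIS   1.750
ND1  HIS   1.600
CD2  HIS   1.750
CE1  HIS   1.750
NE2  HIS   1.600
N    ILE   1.600
CA   ILE   1.750
C    ILE   1.750
O    ILE   1.500
CB   ILE   1.750
CG1  ILE   1.750
CG2  ILE   1.750
CD1  ILE   1.750
N    LEU   1.600
CA   LEU   1.750
C    LEU   1.750
O    LEU   1.500
CB   LEU   1.750
CG   LEU   1.750
CD1  LEU   1.750
CD2  LEU   1.750
N    LYS   1.600
CA   LYS   1.750
C    LYS   1.750
O    LYS   1.500
CB   LYS   1.750
CG   LYS   1.750
CD   LYS   1.750
CE   LYS   1.750
NZ   LYS   1.600
N    MET   1.600
CA   MET   1.750
C    MET   1.750
O    MET   1.500
CB   MET   1.750
CG   MET   1.750
SD   MET   1.850
CE   MET   1.750
N    PHE   1.600
CA   PHE   1.750
C    PHE   1.750
O    PHE   1.500
CB   PHE   1.750
CG   PHE   1.750
CD1  PHE   1.750
CD2  PHE   1.750
CE1  PHE   1.750
CE2  PHE   1.750
CZ   PHE   1.750
N    PRO   1.600
CA   PRO   1.750
C    PRO   1.750
O    PRO   1.500
CB   PRO   1.750
CG   PRO   1.750
CD   PRO   1.750
N    SER   1.600
CA   SER   1.750
C    SER   1.750
O    SER   1.500
CB   SER   1.750
OG   SER   1.500
N    THR   1.600
CA   THR   1.750
C    THR   1.750
O    THR   1.500
CB   THR   1.750
OG1  THR   1.500
CG2  THR   1.750
N    TRP   1.600
CA   TRP   1.750
C    TRP   1.750
O    TRP   1.500
CB   TRP   1.750
CG   TRP   1.750
CD1  TRP   1.750
CD2  TRP   1.750
NE1  TRP   1.600
CE2  TRP   1.750
CE3  TRP   1.750
CZ2  TRP   1.750
CZ3  TRP   1.750
CH2  TRP   1.750
N    TYR   1.600
CA   TYR   1.750
C    TYR   1.750
O    TYR   1.500
CB   TYR   1.750
CG   TYR   1.750
CD1  TYR   1.750
CD2  TYR   1.750
CE1  TYR   1.750
CE2  TYR   1.750
CZ   TYR   1.750
OH   TYR   1.500
N    VAL   1.600
CA   VAL   1.750
C    VAL   1.750
O    VAL   1.500
CB   VAL   1.750
CG1  VAL   1.750
CG2  VAL   1.750
C          1.750
N          1.600
O          1.500
S          1.850
H          1.100
OXT        1.500
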