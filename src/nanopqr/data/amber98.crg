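! amber98 charge subset (CRG) - illustrative parameter subset bundled
! with nanopqr for testing; NOT the published force-field file.
! columns: atom_name [residue_name] charge_e
N    ALA  -0.4000
CA   ALA   0.1000
C    ALA   0.5500
O    ALA  -0.5500
CB   ALA   0.0600
N    ARG  -0.4000
CA   ARG   0.1000
C    ARG   0.5500
O    ARG  -0.5500
CB   ARG   0.0600
CG   ARG   0.0600
CD   ARG   0.0600
NE   ARG  -0.3000
CZ   ARG   0.0600
NH1  ARG  -0.3000
NH2  ARG  -0.3000
N    ASN  -0.4000
CA   ASN   0.1000
C    ASN   0.5500
O    ASN  -0.5500
CB   ASN   0.0600
CG   ASN   0.0600
OD1  ASN  -0.5000
ND2  ASN  -0.3000
N    ASP  -0.4000
CA   ASP   0.1000
C    ASP   0.5500
O    ASP  -0.5500
CB   ASP   0.0600
CG   ASP   0.0600
OD1  ASP  -0.5000
OD2  ASP  -0.5000
N    CYS  -0.4000
CA   CYS   0.1000
C    CYS   0.5500
O    CYS  -0.5500
CB   CYS   0.0600
SG   CYS  -0.2000
N    GLN  -0.4000
CA   GLN   0.1000
C    GLN   0.5500
O    GLN  -0.5500
CB   GLN   0.0600
CG   GLN   0.0600
CD   GLN   0.0600
OE1  GLN  -0.5000
NE2  GLN  -0.3000
N    GLU  -0.4000
CA   GLU   0.1000
C    GLU   0.5500
O    GLU  -0.5500
CB   GLU   0.0600
CG   GLU   0.0600
CD   GLU   0.0600
OE1  GLU  -0.5000
OE2  GLU  -0.5000
N    GLY  -0.4000
CA   GLY   0.1000
C    GLY   0.5500
O    GLY  -0.5500
N    HIS  -0.4000
CA   HIS   0.1000
C    HIS   0.5500
O    HIS  -0.5500
CB   HIS   0.0600
CG   HIS   0.0600
ND1  HIS  -0.3000
CD2  HIS   0.0600
CE1  HIS   0.0600
NE2  HIS  -0.3000
N    ILE  -0.4000
CA   ILE   0.1000
C    ILE   0.5500
O    ILE  -0.5500
CB   ILE   0.0600
CG1  ILE   0.0600
CG2  ILE   0.0600
CD1  ILE   0.0600
N    LEU  -0.4000
CA   LEU   0.1000
C    LEU   0.5500
O    LEU  -0.5500
CB   LEU   0.0600
CG   LEU   0.0600
CD1  LEU   0.0600
CD2  LEU   0.0600
N    LYS  -0.4000
CA   LYS   0.1000
C    LYS   0.5500
O    LYS  -0.5500
CB   LYS   0.0600
CG   LYS   0.0600
CD   LYS   0.0600
CE   LYS   0.0600
NZ   LYS  -0.3000
N    MET  -0.4000
CA   MET   0.1000
C    MET   0.5500
O    MET  -0.5500
CB   MET   0.0600
CG   MET   0.0600
SD   MET  -0.2000
CE   MET   0.0600
N    PHE  -0.4000
CA   PHE   0.1000
C    PHE   0.5500
O    PHE  -0.5500
CB   PHE   0.0600
CG   PHE   0.0600
CD1  PHE   0.0600
CD2  PHE   0.0600
CE1  PHE   0.0600
CE2  PHE   0.0600
CZ   PHE   0.0600
N    PRO  -0.4000
CA   PRO   0.1000
C    PRO   0.5500
O    PRO  -0.5500
CB   PRO   0.0600
CG   PRO   0.0600
CD   PRO   0.0600
N    SER  -0.4000
CA   SER   0.1000
C    SER   0.5500
O    SER  -0.5500
CB   SER   0.0600
OG   SER  -0.5000
N    THR  -0.4000
CA   THR   0.1000
C    THR   0.5500
O    THR  -0.5500
CB   THR   0.0600
OG1  THR  -0.5000
CG2  THR   0.0600
N    TRP  -0.4000
CA   TRP   0.1000
C    TRP   0.5500
O    TRP  -0.5500
CB   TRP   0.0600
CG   TRP   0.0600
CD1  TRP   0.0600
CD2  TRP   0.0600
NE1  TRP  -0.3000
CE2  TRP   0.0600
CE3  TRP   0.0600
CZ2  TRP   0.0600
CZ3  TRP   0.0600
CH2  TRP   0.0600
N    TYR  -0.4000
CA   TYR   0.1000
C    TYR   0.5500
O    TYR  -0.5500
CB   TYR   0.0600
CG   TYR   0.0600
CD1  TYR   0.0600
CD2  TYR   0.0600
CE1  TYR   0.0600
CE2  TYR   0.0600
CZ   TYR   0.0600
OH   TYR  -0.5000
N    VAL  -0.4000
CA   VAL   0.1000
C    VAL   0.5500
O    VAL  -0.5500
CB   VAL   0.0600
CG1  VAL   0.0600
CG2  VAL   0.0600
C          0.0000
N          0.0000
O          0.0000
S          0.0000
H          0.0000
OXT       -0.6500
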