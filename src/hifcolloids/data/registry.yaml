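# Default coarse-grained species registry.
#
# Bead layouts carry only labels (Martini-style bead/atom names), roles and
# relative masses; no interaction parameters.  Glyceride tails are four beads
# each (16-18 carbons at CG resolution), and the layouts satisfy the digestion
# bead-conservation identities: n(TAG)=n(DAG)+n(FA), n(DAG)=2*n(FA).
# Every layout here can be overridden by loading a user registry file.

TC:
  class: bile_salt
  n_tails: 0
  beads:
    - {label: R1, role: tail}
    - {label: R2, role: tail}
    - {label: R3, role: tail}
    - {label: R4, role: tail}
    - {label: TAU, role: head}
TDC:
  class: bile_salt
  n_tails: 0
  beads:
    - {label: R1, role: tail}
    - {label: R2, role: tail}
    - {label: R3, role: tail}
    - {label: R4, role: tail}
    - {label: TAU, role: head}
GC:
  class: bile_salt
  n_tails: 0
  beads:
    - {label: R1, role: tail}
    - {label: R2, role: tail}
    - {label: R3, role: tail}
    - {label: R4, role: tail}
    - {label: GLY, role: head}
GDC:
  class: bile_salt
  n_tails: 0
  beads:
    - {label: R1, role: tail}
    - {label: R2, role: tail}
    - {label: R3, role: tail}
    - {label: R4, role: tail}
    - {label: GLY, role: head}
PPC:
  class: phospholipid
  n_tails: 1
  beads:
    - {label: NC3, role: head}
    - {label: PO4, role: head}
    - {label: GL1, role: linker}
    - {label: C1A, role: tail}
    - {label: C2A, role: tail}
    - {label: C3A, role: tail}
    - {label: C4A, role: tail}
POPC:
  class: phospholipid
  n_tails: 2
  beads:
    - {label: NC3, role: head}
    - {label: PO4, role: head}
    - {label: GL1, role: linker}
    - {label: GL2, role: linker}
    - {label: C1A, role: tail}
    - {label: C2A, role: tail}
    - {label: C3A, role: tail}
    - {label: C4A, role: tail}
    - {label: C1B, role: tail}
    - {label: C2B, role: tail}
    - {label: C3B, role: tail}
    - {label: C4B, role: tail}
FA:
  class: fatty_acid
  n_tails: 1
  beads:
    - {label: COO, role: head}
    - {label: C1, role: tail}
    - {label: C2, role: tail}
    - {label: C3, role: tail}
    - {label: C4, role: tail}
MAG:
  class: MAG
  n_tails: 1
  beads:
    - {label: GL1, role: linker}
    - {label: C1A, role: tail}
    - {label: C2A, role: tail}
    - {label: C3A, role: tail}
    - {label: C4A, role: tail}
DAG:
  class: DAG
  n_tails: 2
  beads:
    - {label: GL1, role: linker}
    - {label: GL2, role: linker}
    - {label: C1A, role: tail}
    - {label: C2A, role: tail}
    - {label: C3A, role: tail}
    - {label: C4A, role: tail}
    - {label: C1B, role: tail}
    - {label: C2B, role: tail}
    - {label: C3B, role: tail}
    - {label: C4B, role: tail}
TAG:
  class: TAG
  n_tails: 3
  beads:
    - {label: GL1, role: linker}
    - {label: GL2, role: linker}
    - {label: GL3, role: linker}
    - {label: C1A, role: tail}
    - {label: C2A, role: tail}
    - {label: C3A, role: tail}
    - {label: C4A, role: tail}
    - {label: C1B, role: tail}
    - {label: C2B, role: tail}
    - {label: C3B, role: tail}
    - {label: C4B, role: tail}
    - {label: C1C, role: tail}
    - {label: C2C, role: tail}
    - {label: C3C, role: tail}
    - {label: C4C, role: tail}
CHOL:
  class: cholesterol
  n_tails: 0
  beads:
    - {label: ROH, role: head}
    - {label: R1, role: tail}
    - {label: R2, role: tail}
    - {label: R3, role: tail}
W:
  class: water
  n_tails: 0
  beads:
    - {label: W, role: solvent}
WF:
  class: antifreeze
  n_tails: 0
  beads:
    - {label: WF, role: solvent}
ION:
  class: ion
  n_tails: 0
  beads:
    - {label: NA, role: solvent}
API:
  class: api
  n_tails: 0
  beads:
    - {label: A1, role: tail}
    - {label: A2, role: tail}
    - {label: A3, role: tail}
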