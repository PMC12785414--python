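; Default water exit-gate taxonomy of the beta-barrel.
; Reg 1: S7A-bulge half-strand (139-145) x S10
; Reg 2: S7B half-strand (146-153) x S10
; Reg 3: S7A-bulge x S8
; Reg 4: S3 x S11
; The S3/S8/S10/S11 residue ranges are editable defaults; only the split
; strand-7 ranges are fixed by the author numbering.

[Reg 1]
segment1 = A 139 145
segment2 = A 193 201

[Reg 2]
segment1 = A 146 153
segment2 = A 193 201

[Reg 3]
segment1 = A 139 145
segment2 = A 157 165

[Reg 4]
segment1 = A 40 48
segment2 = A 210 218
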