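{
 "atom_type_names": [
  "Nbb",
  "CAbb",
  "Cbb",
  "Obb",
  "GlyCA",
  "CB",
  "Cali",
  "Caro",
  "Ccarb",
  "Cgua",
  "Namd",
  "Nring",
  "NzLys",
  "Ngua",
  "Ocarb",
  "Oamd",
  "Ohyd",
  "S"
 ],
 "residue_names": [
  "ALA",
  "ARG",
  "ASN",
  "ASP",
  "CYS",
  "GLN",
  "GLU",
  "GLY",
  "HIS",
  "ILE",
  "LEU",
  "LYS",
  "MET",
  "PHE",
  "PRO",
  "SER",
  "THR",
  "TRP",
  "TYR",
  "VAL"
 ],
 "atom_map": {
  "ALA N": 0,
  "ALA CA": 1,
  "ALA C": 2,
  "ALA O": 3,
  "ALA OXT": 3,
  "ALA CB": 5,
  "ARG N": 0,
  "ARG CA": 1,
  "ARG C": 2,
  "ARG O": 3,
  "ARG OXT": 3,
  "ARG CB": 5,
  "ARG CG": 6,
  "ARG CD": 6,
  "ARG NE": 13,
  "ARG CZ": 9,
  "ARG NH1": 13,
  "ARG NH2": 13,
  "ASN N": 0,
  "ASN CA": 1,
  "ASN C": 2,
  "ASN O": 3,
  "ASN OXT": 3,
  "ASN CB": 5,
  "ASN CG": 8,
  "ASN OD1": 15,
  "ASN ND2": 10,
  "ASP N": 0,
  "ASP CA": 1,
  "ASP C": 2,
  "ASP O": 3,
  "ASP OXT": 3,
  "ASP CB": 5,
  "ASP CG": 8,
  "ASP OD1": 14,
  "ASP OD2": 14,
  "CYS N": 0,
  "CYS CA": 1,
  "CYS C": 2,
  "CYS O": 3,
  "CYS OXT": 3,
  "CYS CB": 5,
  "CYS SG": 17,
  "GLN N": 0,
  "GLN CA": 1,
  "GLN C": 2,
  "GLN O": 3,
  "GLN OXT": 3,
  "GLN CB": 5,
  "GLN CG": 6,
  "GLN CD": 8,
  "GLN OE1": 15,
  "GLN NE2": 10,
  "GLU N": 0,
  "GLU CA": 1,
  "GLU C": 2,
  "GLU O": 3,
  "GLU OXT": 3,
  "GLU CB": 5,
  "GLU CG": 6,
  "GLU CD": 8,
  "GLU OE1": 14,
  "GLU OE2": 14,
  "GLY N": 0,
  "GLY CA": 4,
  "GLY C": 2,
  "GLY O": 3,
  "GLY OXT": 3,
  "HIS N": 0,
  "HIS CA": 1,
  "HIS C": 2,
  "HIS O": 3,
  "HIS OXT": 3,
  "HIS CB": 5,
  "HIS CG": 7,
  "HIS ND1": 11,
  "HIS CD2": 7,
  "HIS CE1": 7,
  "HIS NE2": 11,
  "ILE N": 0,
  "ILE CA": 1,
  "ILE C": 2,
  "ILE O": 3,
  "ILE OXT": 3,
  "ILE CB": 5,
  "ILE CG1": 6,
  "ILE CG2": 6,
  "ILE CD1": 6,
  "ILE CD": 6,
  "LEU N": 0,
  "LEU CA": 1,
  "LEU C": 2,
  "LEU O": 3,
  "LEU OXT": 3,
  "LEU CB": 5,
  "LEU CG": 6,
  "LEU CD1": 6,
  "LEU CD2": 6,
  "LYS N": 0,
  "LYS CA": 1,
  "LYS C": 2,
  "LYS O": 3,
  "LYS OXT": 3,
  "LYS CB": 5,
  "LYS CG": 6,
  "LYS CD": 6,
  "LYS CE": 6,
  "LYS NZ": 12,
  "MET N": 0,
  "MET CA": 1,
  "MET C": 2,
  "MET O": 3,
  "MET OXT": 3,
  "MET CB": 5,
  "MET CG": 6,
  "MET SD": 17,
  "MET CE": 6,
  "PHE N": 0,
  "PHE CA": 1,
  "PHE C": 2,
  "PHE O": 3,
  "PHE OXT": 3,
  "PHE CB": 5,
  "PHE CG": 7,
  "PHE CD1": 7,
  "PHE CD2": 7,
  "PHE CE1": 7,
  "PHE CE2": 7,
  "PHE CZ": 7,
  "PRO N": 0,
  "PRO CA": 1,
  "PRO C": 2,
  "PRO O": 3,
  "PRO OXT": 3,
  "PRO CB": 5,
  "PRO CG": 6,
  "PRO CD": 6,
  "SER N": 0,
  "SER CA": 1,
  "SER C": 2,
  "SER O": 3,
  "SER OXT": 3,
  "SER CB": 5,
  "SER OG": 16,
  "THR N": 0,
  "THR CA": 1,
  "THR C": 2,
  "THR O": 3,
  "THR OXT": 3,
  "THR CB": 5,
  "THR OG1": 16,
  "THR CG2": 6,
  "TRP N": 0,
  "TRP CA": 1,
  "TRP C": 2,
  "TRP O": 3,
  "TRP OXT": 3,
  "TRP CB": 5,
  "TRP CG": 7,
  "TRP CD1": 7,
  "TRP CD2": 7,
  "TRP NE1": 11,
  "TRP CE2": 7,
  "TRP CE3": 7,
  "TRP CZ2": 7,
  "TRP CZ3": 7,
  "TRP CH2": 7,
  "TYR N": 0,
  "TYR CA": 1,
  "TYR C": 2,
  "TYR O": 3,
  "TYR OXT": 3,
  "TYR CB": 5,
  "TYR CG": 7,
  "TYR CD1": 7,
  "TYR CD2": 7,
  "TYR CE1": 7,
  "TYR CE2": 7,
  "TYR CZ": 7,
  "TYR OH": 16,
  "VAL N": 0,
  "VAL CA": 1,
  "VAL C": 2,
  "VAL O": 3,
  "VAL OXT": 3,
  "VAL CB": 5,
  "VAL CG1": 6,
  "VAL CG2": 6
 },
 "acp": [
  [
   0.6,
   0.25,
   0.4,
   0.6,
   0.25,
   0.1,
   0.0,
   0.05,
   0.45,
   0.45,
   0.65,
   0.55,
   0.8,
   0.75,
   0.85,
   0.7,
   0.65,
   0.15
  ],
  [
   0.25,
   -0.1,
   0.05,
   0.25,
   -0.1,
   -0.25,
   -0.35,
   -0.3,
   0.1,
   0.1,
   0.3,
   0.2,
   0.45,
   0.4,
   0.5,
   0.35,
   0.3,
   -0.2
  ],
  [
   0.4,
   0.05,
   0.2,
   0.4,
   0.05,
   -0.1,
   -0.2,
   -0.15,
   0.25,
   0.25,
   0.45,
   0.35,
   0.6,
   0.55,
   0.65,
   0.5,
   0.45,
   -0.05
  ],
  [
   0.6,
   0.25,
   0.4,
   0.6,
   0.25,
   0.1,
   0.0,
   0.05,
   0.45,
   0.45,
   0.65,
   0.55,
   0.8,
   0.75,
   0.85,
   0.7,
   0.65,
   0.15
  ],
  [
   0.25,
   -0.1,
   0.05,
   0.25,
   -0.1,
   -0.25,
   -0.35,
   -0.3,
   0.1,
   0.1,
   0.3,
   0.2,
   0.45,
   0.4,
   0.5,
   0.35,
   0.3,
   -0.2
  ],
  [
   0.1,
   -0.25,
   -0.1,
   0.1,
   -0.25,
   -0.4,
   -0.5,
   -0.45,
   -0.05,
   -0.05,
   0.15,
   0.05,
   0.3,
   0.25,
   0.35,
   0.2,
   0.15,
   -0.35
  ],
  [
   0.0,
   -0.35,
   -0.2,
   0.0,
   -0.35,
   -0.5,
   -0.6,
   -0.55,
   -0.15,
   -0.15,
   0.05,
   -0.05,
   0.2,
   0.15,
   0.25,
   0.1,
   0.05,
   -0.45
  ],
  [
   0.05,
   -0.3,
   -0.15,
   0.05,
   -0.3,
   -0.45,
   -0.55,
   -0.5,
   -0.1,
   -0.1,
   0.1,
   0.0,
   0.25,
   0.2,
   0.3,
   0.15,
   0.1,
   -0.4
  ],
  [
   0.45,
   0.1,
   0.25,
   0.45,
   0.1,
   -0.05,
   -0.15,
   -0.1,
   0.3,
   0.3,
   0.5,
   0.4,
   0.65,
   0.6,
   0.7,
   0.55,
   0.5,
   0.0
  ],
  [
   0.45,
   0.1,
   0.25,
   0.45,
   0.1,
   -0.05,
   -0.15,
   -0.1,
   0.3,
   0.3,
   0.5,
   0.4,
   0.65,
   0.6,
   0.7,
   0.55,
   0.5,
   0.0
  ],
  [
   0.65,
   0.3,
   0.45,
   0.65,
   0.3,
   0.15,
   0.05,
   0.1,
   0.5,
   0.5,
   0.7,
   0.6,
   0.85,
   0.8,
   0.9,
   0.75,
   0.7,
   0.2
  ],
  [
   0.55,
   0.2,
   0.35,
   0.55,
   0.2,
   0.05,
   -0.05,
   0.0,
   0.4,
   0.4,
   0.6,
   0.5,
   0.75,
   0.7,
   0.8,
   0.65,
   0.6,
   0.1
  ],
  [
   0.8,
   0.45,
   0.6,
   0.8,
   0.45,
   0.3,
   0.2,
   0.25,
   0.65,
   0.65,
   0.85,
   0.75,
   1.0,
   0.95,
   1.05,
   0.9,
   0.85,
   0.35
  ],
  [
   0.75,
   0.4,
   0.55,
   0.75,
   0.4,
   0.25,
   0.15,
   0.2,
   0.6,
   0.6,
   0.8,
   0.7,
   0.95,
   0.9,
   1.0,
   0.85,
   0.8,
   0.3
  ],
  [
   0.85,
   0.5,
   0.65,
   0.85,
   0.5,
   0.35,
   0.25,
   0.3,
   0.7,
   0.7,
   0.9,
   0.8,
   1.05,
   1.0,
   1.1,
   0.95,
   0.9,
   0.4
  ],
  [
   0.7,
   0.35,
   0.5,
   0.7,
   0.35,
   0.2,
   0.1,
   0.15,
   0.55,
   0.55,
   0.75,
   0.65,
   0.9,
   0.85,
   0.95,
   0.8,
   0.75,
   0.25
  ],
  [
   0.65,
   0.3,
   0.45,
   0.65,
   0.3,
   0.15,
   0.05,
   0.1,
   0.5,
   0.5,
   0.7,
   0.6,
   0.85,
   0.8,
   0.9,
   0.75,
   0.7,
   0.2
  ],
  [
   0.15,
   -0.2,
   -0.05,
   0.15,
   -0.2,
   -0.35,
   -0.45,
   -0.4,
   0.0,
   0.0,
   0.2,
   0.1,
   0.35,
   0.3,
   0.4,
   0.25,
   0.2,
   -0.3
  ]
 ],
 "default_charge": {
  "LYS NZ": 1.0,
  "ARG NH1": 0.5,
  "ARG NH2": 0.5,
  "ASP OD1": -0.5,
  "ASP OD2": -0.5,
  "GLU OE1": -0.5,
  "GLU OE2": -0.5,
  "HIS ND1": 0.25,
  "HIS NE2": 0.25
 }
}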