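# Batch compositions of the three cefdinir formulations (masses in mg).
# F1: spray-dried polymeric solid dispersion (drug:PVP 1:2 w/w, NaOH for the
#     sodium salt); F2: mesoporous silica (SBA-15) solvent-immersion system;
# F3: spray-dried co-amorphous system with amino-acid coformers.
F1:
  drug: Cefdinir
  components:
    Cefdinir: 300.0
    PVP K30: 600.0
    NaOH: 30.35
F2:
  drug: Cefdinir
  components:
    Cefdinir: 300.0
    SBA-15: 507.2
F3:
  drug: Cefdinir
  components:
    Cefdinir: 300.0
    L-arginine: 174.20
    L-phenylalanine: 165.19
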