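#!name: cd4t
#!provenance: reconstructed-from-main-text
#!cell_type: CD4T
# Reduced Boolean model of CD4+ T helper differentiation and plasticity in
# the VAT, in the tradition of minimal master-regulator/cytokine circuits:
# each lineage couples a master transcription factor to its signature
# cytokine, with cross-lineage mutual inhibition.  Insulin promotes
# effector (notably Th17) programs and restrains FoxP3 induction;
# extracellular ceramide blunts Th1 priming and lifts the insulin brake on
# FoxP3 (regulatory lineages recover under lipotoxic conditions).
targets, factors
# --- environmental inputs ---
IL12e, IL12e
IFNGe, IFNGe
IL2e, IL2e
IL4e, IL4e
IL6e, IL6e
TGFBe, TGFBe
IL10e, IL10e
INS, INS
CERe, CERe
# --- master regulators ---
TBET, ((IL12e & IFNGe & ! CERe) | (TBET & IFNG)) & ! GATA3 & ! FOXP3
GATA3, ((IL4e & IL2e) | (IL4e & INS) | (GATA3 & IL4)) & ! TBET & ! FOXP3
RORGT, ((IL6e & TGFBe) | (INS & TGFBe) | (RORGT & TGFBe)) & ! FOXP3 & ! TBET & ! GATA3
PU1, ((IL4e & TGFBe) | (PU1 & TGFBe)) & ! GATA3 & ! TBET & ! FOXP3
FOXP3, (IL2e & TGFBe & ! IL6e & ! RORGT & ! (INS & ! CERe)) & ! TBET & ! GATA3
# --- signature cytokines ---
# IFN-g keeps an autocrine memory unless suppressed by Th2/regulatory
# products; the asymmetry with IL-4 (which IFN-g shuts down, but not vice
# versa) reflects the dominance of type-1 over type-2 memory
IFNG, TBET | (IFNG & ! TGFB & ! GATA3 & ! IL10)
IL4, GATA3 | (IL4 & FOXP3 & ! IFNG & ! TGFB)
IL9, PU1
IL17, RORGT
IL10, (FOXP3 & (IL10 | TGFB)) | IL10e
TGFB, (FOXP3 & TGFBe & ! IFNG & ! IL4) | (TGFB & TGFBe & ! IFNG & ! IL4)
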