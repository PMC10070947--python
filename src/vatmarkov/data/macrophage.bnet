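#!name: macrophage
#!provenance: reconstructed-from-main-text
#!cell_type: macrophage
# Reduced Boolean model of a VAT-resident macrophage.  Classical (M1)
# polarization runs through NF-kB (TLR4/TNF) plus STAT1 (IFN-g); alternative
# (M2) polarization through STAT6 (IL-4/IL-13); IL-10/STAT3 suppresses
# NF-kB; GM-CSF with IL-4 and IL-10 drives the mixed iNOS+/Arg1+
# tumor-associated program without IL-12/IFN-g production (M2-TAM).
targets, factors
# --- environmental inputs ---
TLR4, TLR4
IFNGe, IFNGe
IL4e, IL4e
IL13e, IL13e
IL10e, IL10e
IL6e, IL6e
TNFe, TNFe
GMCSF, GMCSF
INS, INS
CERe, CERe
# --- signalling ---
STAT6, IL4e | IL13e
STAT3, IL10e
STAT1, IFNGe | IFNG
NFKB, (TLR4 | TNFe | CERe | (INS & INOS)) & ! STAT3
# --- polarization markers ---
# iNOS: classical activation, the mixed TAM program, or self-sustained
# while an activating context (NF-kB or STAT1) persists
INOS, (NFKB & STAT1) | (GMCSF & STAT6 & STAT3) | (INOS & (NFKB | STAT1))
# Arg1: alternative activation, with STAT6/STAT3-dependent memory, vetoed
# by full classical activation
ARG1, (STAT6 | (ARG1 & (STAT6 | STAT3))) & ! (NFKB & STAT1 & ! GMCSF)
# M1 effector cytokines; the autocrine IL-12/IFN-g loop lets a committed
# classical program persist after the inducing stimulus is gone
IL12, (NFKB | INOS) & STAT1 & ! STAT3 & ! STAT6
IFNG, IL12
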