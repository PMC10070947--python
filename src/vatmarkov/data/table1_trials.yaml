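# Qualitative validation grid: expected phenotype-frequency relations per
# microenvironment, scored at each noise level of the robustness set.
# "conditions" map condition names to the input nodes clamped to 1
# (all other declared inputs are clamped to 0).
CD4T:
  conditions:
    "None": {}
    "IL-12 + IFN-g": {IL12e: 1, IFNGe: 1}
    "IL-2 + IL-4": {IL2e: 1, IL4e: 1}
    "IL-4 + TGF-b": {IL4e: 1, TGFBe: 1}
    "IL-6 + TGF-b": {IL6e: 1, TGFBe: 1}
    "IL-2 + TGF-b": {IL2e: 1, TGFBe: 1}
  trials:
    - {condition: "None", relation: "Th0 > others"}
    - {condition: "None", relation: "Others = 0%", baseline: "Th0"}
    - {condition: "IL-12 + IFN-g", relation: "Th1 > Th2"}
    - {condition: "IL-2 + IL-4", relation: "Th2 > Th1"}
    - {condition: "IL-4 + TGF-b", relation: "Th9 > Th0"}
    - {condition: "IL-6 + TGF-b", relation: "Th17 > Th2"}
    - {condition: "IL-2 + TGF-b", relation: "iTreg > Th1R"}
    - {condition: "IL-2 + TGF-b", relation: "iTreg > Th2R"}
    - {condition: "IL-2 + TGF-b", relation: "Th1R > Th2R"}
macrophage:
  conditions:
    "None": {}
    "TLR4 + IFN-g": {TLR4: 1, IFNGe: 1}
    "IL-4 + IL-13": {IL4e: 1, IL13e: 1}
    "IL-4 + IL-10 + GM-CSF": {IL4e: 1, IL10e: 1, GMCSF: 1}
  trials:
    - {condition: "None", relation: "M0 > M2"}
    - {condition: "TLR4 + IFN-g", relation: "M1 > M2"}
    - {condition: "IL-4 + IL-13", relation: "M2 > M1"}
    - {condition: "IL-4 + IL-10 + GM-CSF", relation: "M2-TAM > M1"}
adipocyte:
  conditions:
    "None": {}
    "Inducer": {INDUCER: 1}
    "Insulin": {INS: 1}
    "Insulin + external TNF": {INS: 1, TNFe: 1}
  trials:
    - {condition: "None", relation: "TNF- > TNF+"}
    - {condition: "Inducer", relation: "TNF+ > TNF-"}
    - {condition: "Insulin", relation: "GLUT4+ > GLUT4-"}
    - {condition: "Insulin + external TNF", relation: "GLUT4- > GLUT4+"}
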