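# Microenvironment catalogs for the physiological contexts, per cell type.
# Each catalog is a set of input clampings drawn from the context's
# characteristic cytokine/hormone profile (lean VAT: low IL-6/TNF, high
# IL-4/IL-10/IL-13/TGF-b, basal IL-12/IFN-g, low TNFR2, no plasma ceramide;
# obese VAT: high IL-6/TNF, more IL-2 and IL-10, less IL-4, high TNFR2;
# diabetic VAT: the obese catalog plus high plasma ceramide).  Boolean
# models admit only present/absent, so "high/low levels" binarize to 1/0.
# Every scenario is run with and without insulin and the per-microenvironment
# stationary distributions are averaged.
lean:
  CD4T:
    "IL-4 + TGF-b": {IL4e: 1, TGFBe: 1}
    "IL-10 + TGF-b": {IL10e: 1, TGFBe: 1}
    "IL-4 + IL-10": {IL4e: 1, IL10e: 1}
    "basal IL-12 + IFN-g": {IL12e: 1, IFNGe: 1}
  macrophage:
    "TLR4 + basal IFN-g": {TLR4: 1, IFNGe: 1}
    "IL-4 + IL-13": {IL4e: 1, IL13e: 1}
    "IL-4 + IL-10": {IL4e: 1, IL10e: 1}
    "TLR4 + IL-10": {TLR4: 1, IL10e: 1}
  adipocyte:
    "quiet": {}
    "IL-4": {IL4e: 1}
    "IL-10": {IL10e: 1}
    "basal IFN-g": {IFNGe: 1}
obese:
  CD4T:
    "IL-6 + TGF-b": {IL6e: 1, TGFBe: 1}
    "IL-2 + IL-6": {IL2e: 1, IL6e: 1}
    "IL-2 + IL-10": {IL2e: 1, IL10e: 1}
    "IL-2 + TGF-b": {IL2e: 1, TGFBe: 1}
  macrophage:
    "TLR4 + TNF": {TLR4: 1, TNFe: 1}
    "TLR4 + IL-6": {TLR4: 1, IL6e: 1}
    "TNF + IL-10": {TNFe: 1, IL10e: 1}
    "TLR4 + IFN-g": {TLR4: 1, IFNGe: 1}
  adipocyte:
    "TNF, TNFR2-high": {TNFe: 1, TNFR2: 1}
    "IL-6, TNFR2-high": {IL6e: 1, TNFR2: 1}
    "TNF + IL-6, TNFR2-high": {TNFe: 1, IL6e: 1, TNFR2: 1}
    "TNF + IL-10, TNFR2-high": {TNFe: 1, IL10e: 1, TNFR2: 1}
# therapy simulations on adipocytes: severe inflammation (high TNF, IL-6 and
# IFN-g) with insulin present; neutralizing antibodies turn the target node
# off, over-activation turns it on for all time steps
therapies:
  base_condition: {TNFe: 1, IL6e: 1, IFNGe: 1}
  treatments:
    "untreated": {}
    "anti-TNF antibody": {TNFe: 0}
    "anti-IL-6 antibody": {IL6e: 0}
    "anti-IL-1b antibody": {IL1B: 0}
    "IL-10 therapy": {IL10e: 1}
    "adiponectin over-activation": {ADIPO: 1}
    "PPARg over-activation": {PPARG: 1}
    "intracellular ceramide knockout": {CERI: 0}
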