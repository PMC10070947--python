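#!name: adipocyte
#!provenance: reconstructed-from-main-text
#!cell_type: adipocyte
# Reduced Boolean model of a VAT adipocyte.  Every rule is motivated by the
# documented causal spine: insulin -> receptor pathway -> GLUT4
# translocation; TNF/IL-6/IFN-g -> inflammatory (NF-kB) pathway ->
# intracellular ceramide -> inhibition of the insulin pathway, self-
# sustained by positive feedback; adiponectin -> ceramide degradation;
# IL-10/IL-4 -> inflammation suppression; TNFR2 amplifies autocrine TNF and
# IL-1b signalling; CTGF marks hypertrophic (inflamed, enlarged) cells.
targets, factors
# --- environmental inputs (clamped by microenvironments) ---
INS, INS
TNFe, TNFe
IL6e, IL6e
IFNGe, IFNGe
IL10e, IL10e
IL4e, IL4e
CERe, CERe
INDUCER, INDUCER
TNFR2, TNFR2
# --- intracellular nodes ---
# inflammatory pathway: driven by external cytokines or the inflammation
# inducer; autocrine TNF/IL-1b loops need the type-2 TNF receptor;
# suppressed by anti-inflammatory interleukins — except under severe
# (triple-cytokine) inflammation, which IL-10/IL-4 alone cannot quench
NFKB, ((TNFe | IL6e | IFNGe | INDUCER | (TNF & TNFR2) | (IL1B & TNFR2)) & ! (IL10e | IL4e)) | (TNFe & IL6e & IFNGe)
TNF, NFKB
IL1B, NFKB
# intracellular ceramide: switched on by inflammation (or extracellular
# ceramide sensed through TNFR2-bearing membranes), self-sustaining through
# its positive feedback loops, degraded by adiponectin-receptor signalling
CERI, (NFKB | CERI | (CERe & TNFR2)) & ! ADIPO
# PPARg and adiponectin: the anti-inflammatory, insulin-sensitizing axis
PPARG, ! NFKB & ! CERI
ADIPO, PPARG
# insulin receptor substrate signalling is blocked by ceramide, not by
# inflammation directly; GLUT4 translocation reports insulin responsiveness
IRS, INS & ! CERI
GLUT4, IRS
# hypertrophy marker: sustained inflammation on ceramide-loaded or
# TNFR2-high cells
CTGF, NFKB & (TNFR2 | CERI)
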