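"""Published worked-example inputs for the allele-responsiveness analysis.

Printed log2 fold-change pairs for genes up-regulated by Al stress at least
twofold more strongly under the Azucena (resistant) ART1 allele than under
the IR64 (sensitive) allele, in each genetic background.  Each tuple is
(gene id, log2FC under the resistant allele, log2FC under the sensitive
allele): in the Azucena background the resistant-allele carrier is Azucena
itself and the sensitive-allele carrier is the NIL AZU[IR64-12.1]; in the
IR64 background the carriers are the NIL IR64[AZU-12.1] and IR64.

The degenerate binding-site motifs of the ART1 transcription factor are the
experimentally defined element GGNVS and its less degenerate form GGYMS.
"""

# Azucena genetic background: (gene, log2FC Azucena, log2FC NIL AZU[IR64-12.1])
AZUCENA_BACKGROUND_TWOFOLD = [
    ("LOC_Os12g38270", 3.25, 0.79),
    ("LOC_Os10g38340", 3.20, 0.74),
    ("LOC_Os03g16030", 3.16, 0.90),
    ("LOC_Os01g43750", 2.89, 0.85),
    ("LOC_Os08g05960", 2.80, 0.86),
    ("LOC_Os08g05970", 2.95, 1.02),
    ("ChrSy.fgenesh.gene.47", 2.51, 0.65),
    ("LOC_Os03g16020", 2.62, 0.79),
    ("LOC_Os01g43774", 2.38, 0.78),
    ("LOC_Os04g27060", 2.12, 0.53),
    ("LOC_Os12g38290", 2.77, 1.20),
    ("LOC_Os08g05980", 1.30, 0.26),
]

# IR64 genetic background: (gene, log2FC NIL IR64[AZU-12.1], log2FC IR64)
IR64_BACKGROUND_TWOFOLD = [
    ("LOC_Os06g19130", 2.31, 0.88),
    ("LOC_Os05g11320", 1.16, -0.13),
    ("LOC_Os01g69010", 4.79, 3.56),
    ("LOC_Os04g01690", 1.87, 0.65),
    ("LOC_Os05g33900", 1.09, -0.04),
    ("LOC_Os12g38290", 1.66, 0.58),
    ("LOC_Os04g41750", 2.92, 1.85),
    ("LOC_Os11g41840", 1.28, 0.27),
    ("LOC_Os06g39700", 1.21, 0.21),
    ("LOC_Os02g09390", 2.65, 1.65),
]

ART1_MOTIF = "GGNVS"
ART1_MOTIF_STRICT = "GGYMS"
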