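"""Built-in gene modules.

Self-renew and NK-like lists follow the longitudinal skewing analysis of the
engineered-cell trial cohort; the blast module flags recipient-origin
leukemic cells in a sex-mismatched transplant (CD34+ XIST+ WT1+).
"""

from tcellfate.dataio import ModuleSignature

SELF_RENEW_GENES = ["TCF7", "LEF1", "SELL", "CCR7", "BCL2", "IL7R", "CD27", "CD28"]
NK_LIKE_GENES = ["ZEB2", "S1PR5", "CX3CR1", "KLRG1", "NKG7", "FCRL6", "KLRD1", "ADGRG1"]
BLAST_GENES = ["CD34", "XIST", "WT1"]

#: name of the engineered-TCR transgene feature in the expression panel
TRANSGENE = "TCRC4"

SELF_RENEW = ModuleSignature("self_renew", SELF_RENEW_GENES)
NK_LIKE = ModuleSignature("nk_like", NK_LIKE_GENES)
BLAST = ModuleSignature("blast", BLAST_GENES)

BUILTIN = {s.name: s for s in (SELF_RENEW, NK_LIKE, BLAST)}
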