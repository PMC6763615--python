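"""Target lists for the two built-in membrane types.

The RTK membrane captures 49 receptor tyrosine kinases through a pan
anti-phospho-tyrosine readout, so no per-analyte site annotation applies.
The MAPK membrane captures 26 downstream signalling molecules with
site-specific detection antibodies; 9 of them are MAP kinases proper
(ERK, JNK and p38 family members).
"""

# 49 receptor tyrosine kinases (pan-pTyr detection; no site annotation).
RTK_TARGETS: tuple[str, ...] = (
    "EGFR",
    "ErbB2",
    "ErbB3",
    "ErbB4",
    "FGFR1",
    "FGFR2a",
    "FGFR3",
    "FGFR4",
    "InsR",
    "IGF-1R",
    "Axl",
    "Dtk",
    "Mer",
    "HGFR",
    "MSPR",
    "PDGFRa",
    "PDGFRb",
    "SCFR",
    "Flt-3",
    "M-CSFR",
    "c-Ret",
    "ROR1",
    "ROR2",
    "Tie-1",
    "Tie-2",
    "TrkA",
    "TrkB",
    "TrkC",
    "VEGFR1",
    "VEGFR2",
    "VEGFR3",
    "MuSK",
    "EphA1",
    "EphA2",
    "EphA3",
    "EphA4",
    "EphA5",
    "EphA6",
    "EphA7",
    "EphA10",
    "EphB1",
    "EphB2",
    "EphB3",
    "EphB4",
    "EphB6",
    "ALK",
    "DDR1",
    "DDR2",
    "RYK",
)

# 26 downstream signalling molecules: name -> (phospho sites, is MAPK).
MAPK_TARGETS: dict[str, tuple[str, bool]] = {
    "Akt1": ("S473", False),
    "Akt2": ("S474", False),
    "Akt3": ("S472", False),
    "Akt pan": ("S473/S474/S472", False),
    "CREB": ("S133", False),
    "ERK1": ("T202/Y204", True),
    "ERK2": ("T185/Y187", True),
    "GSK-3a/b": ("S21/S9", False),
    "GSK-3b": ("S9", False),
    "HSP27": ("S78/S82", False),
    "JNK1": ("T183/Y185", True),
    "JNK2": ("T183/Y185", True),
    "JNK3": ("T221/Y223", True),
    "JNK pan": ("T183/Y185, T221/Y223", False),
    "MKK3": ("S218/T222", False),
    "MKK6": ("S207/T211", False),
    "MSK2": ("S360", False),
    "p38a": ("T180/Y182", True),
    "p38b": ("T180/Y182", True),
    "p38d": ("T180/Y182", True),
    "p38g": ("T183/Y185", True),
    "p53": ("S46", False),
    "p70 S6K": ("T421/S424", False),
    "RSK1": ("S380", False),
    "RSK2": ("S386", False),
    "TOR": ("S2448", False),
}

POSITIVE_REFERENCE_NAMES: tuple[str, ...] = (
    "Reference-1",
    "Reference-2",
    "Reference-3",
)
NEGATIVE_CONTROL_NAME: str = "PBS"
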