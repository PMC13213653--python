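"""Electrode montage constants for the 19-channel 10-20 dry-sensor layout."""

# 19 scalp positions of the 10-20 system (mastoid references excluded).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "T3", "C3", "CZ", "C4", "T4",
    "P7", "P3", "PZ", "P4", "P8",
    "O1", "O2",
)

# Midline electrodes carrying the dominant P300 response.
CENTRAL_ELECTRODES: tuple[str, ...] = ("FZ", "CZ", "PZ")

ROLES: tuple[str, ...] = ("Shooter", "Bait")
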