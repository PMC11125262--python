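"""The 22-electrode 10-20 montage used by the BCI Competition IV 2a recordings.

Electrode indices are 0-based internally; user-facing I/O (CLI, serialized
channel sets) uses the conventional 1..22 numbering of this list.
"""

MONTAGE_22 = [
    "Fz",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2",
    "POz",
]

assert len(MONTAGE_22) == 22


def to_user_indices(indices):
    """0-based internal indices -> 1-based user-facing channel numbers."""
    return [int(i) + 1 for i in indices]


def from_user_indices(indices):
    """1-based user-facing channel numbers -> 0-based internal indices."""
    return [int(i) - 1 for i in indices]
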