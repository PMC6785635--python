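"""Three-scale physicochemical amino-acid descriptors (z-scales).

The z-scales are principal-component summaries of 29 measured physicochemical
properties of the 20 natural amino acids (Hellberg et al., J. Med. Chem. 30,
1987): z1 tracks hydrophilicity, z2 steric bulk, z3 polarity/electronic
properties.  They are the standard residue encoding in proteochemometric
modelling.  Alternative tables can be passed anywhere a ``ZScaleTable`` is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ZScaleTable:
    """Per-amino-acid (z1, z2, z3) descriptor triples, with a version tag."""

    values: dict[str, tuple[float, float, float]]
    version: str = "custom"

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"z-scale table needs 20 entries, got {len(self.values)}")

    def __getitem__(self, aa: str) -> tuple[float, float, float]:
        return self.values[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.values


#: Hellberg et al. (1987) three-component z-scales for the 20 amino acids.
HELLBERG_1987 = ZScaleTable(
    version="hellberg-1987",
    values={
        "A": (0.07, -1.73, 0.09),
        "V": (-2.69, -2.53, -1.29),
        "L": (-4.19, -1.03, -0.98),
        "I": (-4.44, -1.68, -1.03),
        "P": (-1.22, 0.88, 2.23),
        "F": (-4.92, 1.30, 0.45),
        "W": (-4.75, 3.65, 0.85),
        "M": (-2.49, -0.27, -0.41),
        "K": (2.84, 1.41, -3.14),
        "R": (2.88, 2.52, -3.44),
        "H": (2.41, 1.74, 1.11),
        "G": (2.23, -5.36, 0.30),
        "S": (1.96, -1.63, 0.57),
        "T": (0.92, -2.09, -1.40),
        "C": (0.71, -0.97, 4.13),
        "Y": (-1.39, 2.32, 0.01),
        "N": (3.22, 1.45, 0.84),
        "Q": (2.18, 0.53, -1.14),
        "D": (3.64, 1.13, 2.36),
        "E": (3.08, 0.39, -0.07),
    },
)

DEFAULT_TABLE = HELLBERG_1987
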