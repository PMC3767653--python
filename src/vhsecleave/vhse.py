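"""VHSE amino-acid descriptors and residue-window encoding.

VHSE (principal-component score Vectors of Hydrophobic, Steric, and
Electronic properties) assigns each of the 20 canonical amino acids eight
dimensionless scores obtained by PCA of 50 physicochemical properties:
VHSE1/VHSE2 summarise hydrophobicity, VHSE3/VHSE4 steric bulk, and
VHSE5-VHSE8 electronic character.  Because they are PCA scores of
auto-scaled property matrices, each column is (up to rounding of the
published constants) centered on zero over the 20 residues.

The descriptor table is a fixed parameter of the method and is embedded
here as data; it is not read from user files.  Only the first component of
each property block (VHSE1, VHSE3, VHSE5) is used by the default cleavage
model, but all eight are available.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "VHSE_TABLE",
    "CANONICAL_RESIDUES",
    "DEFAULT_SELECTION",
    "DescriptorUnavailableError",
    "lookup",
    "encode_window",
    "is_canonical",
    "validate_selection",
    "export_table_tsv",
]

# residue -> (VHSE1..VHSE8); dimensionless PCA scores.
VHSE_TABLE: dict[str, tuple[float, ...]] = {
    "A": (0.15, -1.11, -1.35, -0.92, 0.02, -0.91, 0.36, -0.48),
    "R": (-1.47, 1.45, 1.24, 1.27, 1.55, 1.47, 1.30, 0.83),
    "N": (-0.99, 0.00, -0.37, 0.69, -0.55, 0.85, 0.73, -0.80),
    "D": (-1.15, 0.67, -0.41, -0.01, -2.68, 1.31, 0.03, 0.56),
    "C": (0.18, -1.67, -0.46, -0.21, 0.00, 1.20, -1.61, -0.19),
    "Q": (-0.96, 0.12, 0.18, 0.16, 0.09, 0.42, -0.20, -0.41),
    "E": (-1.18, 0.40, 0.10, 0.36, -2.16, -0.17, 0.91, 0.02),
    "G": (-0.20, -1.53, -2.63, 2.28, -0.53, -1.18, 2.01, -1.34),
    "H": (-0.43, -0.25, 0.37, 0.19, 0.51, 1.28, 0.93, 0.65),
    "I": (1.27, -0.14, 0.30, -1.80, 0.30, -1.61, -0.16, -0.13),
    "L": (1.36, 0.07, 0.26, -0.80, 0.22, -1.37, 0.08, -0.62),
    "K": (-1.17, 0.70, 0.70, 0.80, 1.64, 0.67, 1.63, 0.13),
    "M": (1.01, -0.53, 0.43, 0.00, 0.23, 0.10, -0.86, -0.68),
    "F": (1.52, 0.61, 0.96, -0.16, 0.25, 0.28, -1.33, -0.20),
    "P": (0.22, -0.17, -0.50, 0.05, -0.01, -1.34, -0.19, 3.56),
    "S": (-0.67, -0.86, -1.07, -0.41, -0.32, 0.27, -0.64, 0.11),
    "T": (-0.34, -0.51, -0.55, -1.06, 0.01, -0.01, -0.79, 0.39),
    "W": (1.50, 2.06, 1.79, 0.75, 0.75, -0.13, -1.06, -0.85),
    "Y": (0.61, 1.60, 1.17, 0.73, 0.53, 0.25, -0.96, -0.52),
    "V": (0.76, -0.92, 0.17, -1.91, 0.22, -1.40, -0.24, -0.03),
}

CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: hydrophobic (VHSE1), steric (VHSE3) and electronic (VHSE5) lead components
DEFAULT_SELECTION: tuple[int, ...] = (1, 3, 5)


class DescriptorUnavailableError(KeyError):
    """Raised when a residue has no VHSE descriptor (non-canonical code)."""

    def __init__(self, residue: str, position: int | None = None):
        self.residue = residue
        self.position = position
        where = "" if position is None else f" at window position {position}"
        super().__init__(
            f"no VHSE descriptor for residue {residue!r}{where}; "
            "only the 20 canonical one-letter codes are defined"
        )


def is_canonical(sequence: str) -> bool:
    """True if every residue of ``sequence`` has a VHSE descriptor."""
    return all(r in VHSE_TABLE for r in sequence)


def validate_selection(selection: Sequence[int]) -> tuple[int, ...]:
    """Validate a component selection: non-empty, strictly increasing, in 1..8."""
    sel = tuple(int(c) for c in selection)
    if not sel:
        raise ValueError("component selection must be non-empty")
    if any(c < 1 or c > 8 for c in sel):
        raise ValueError(f"VHSE components must lie in 1..8, got {sel}")
    if any(b <= a for a, b in zip(sel, sel[1:])):
        raise ValueError(f"component selection must be strictly increasing, got {sel}")
    return sel


def lookup(residue: str, component: int) -> float:
    """Return the VHSE score of one residue.

    Parameters
    ----------
    residue
        One-letter code of a canonical amino acid.
    component
        VHSE component number, 1..8.
    """
    if not isinstance(component, (int, np.integer)) or not 1 <= component <= 8:
        raise ValueError(f"VHSE component must be an integer in 1..8, got {component!r}")
    try:
        row = VHSE_TABLE[residue]
    except KeyError:
        raise DescriptorUnavailableError(residue) from None
    return row[component - 1]


def encode_window(window: str, selection: Sequence[int] = DEFAULT_SELECTION) -> np.ndarray:
    """Encode a residue window as a flat descriptor vector.

    The layout is position-major: all selected components of the first
    (most upstream) residue, then of the second, and so on downstream.
    With a +/-14 window and the default three components this yields the
    84-variable representation used for cleavage-sample classification.
    """
    sel = validate_selection(selection)
    out = np.empty(len(window) * len(sel), dtype=float)
    k = 0
    for pos, residue in enumerate(window):
        try:
            row = VHSE_TABLE[residue]
        except KeyError:
            raise DescriptorUnavailableError(residue, position=pos) from None
        for comp in sel:
            out[k] = row[comp - 1]
            k += 1
    return out


def export_table_tsv(path) -> None:
    """Write the descriptor table as TSV (residue, VHSE1..VHSE8) for audit."""
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(f"VHSE{i}" for i in range(1, 9)) + "\n")
        for residue in CANONICAL_RESIDUES:
            row = VHSE_TABLE[residue]
            fh.write(residue + "\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")
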