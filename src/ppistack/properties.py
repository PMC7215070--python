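"""Physicochemical property tables and the seven-group amino-acid alphabet.

The autocovariance encoder uses seven per-residue physicochemical scales:
hydrophobicity (H1), hydrophilicity (H2), side-chain volume (VSC), polarity
(P1), polarizability (P2), solvent-accessible surface area (SASA) and the net
charge index of side chains (NCI).  The numeric values are the scales
conventionally used with Guo-style autocovariance encodings; per-column
provenance is noted below.  The pseudo-amino-acid-composition encoder uses
hydrophobicity, hydrophilicity and side-chain mass.

All scales are standardized (zero mean, unit variance over the 20 standard
amino acids) before use, which makes the encodings invariant to the affine
scale of the published tables.
"""

from __future__ import annotations

import numpy as np

from .records import STANDARD_AA

# H1: hydrophobicity (Tanford-style consensus scale)
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

# H2: hydrophilicity (Hopp-Woods)
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

# VSC: volume of side chains (A^3)
_SIDE_CHAIN_VOLUME = {
    "A": 27.5, "C": 44.6, "D": 40.0, "E": 62.0, "F": 115.5,
    "G": 0.0, "H": 79.0, "I": 93.5, "K": 100.0, "L": 93.5,
    "M": 94.1, "N": 58.7, "P": 41.9, "Q": 80.7, "R": 105.0,
    "S": 29.3, "T": 51.3, "V": 71.5, "W": 145.5, "Y": 117.3,
}

# P1: polarity (Grantham)
_POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

# P2: polarizability (Charton-Charton)
_POLARIZABILITY = {
    "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290,
    "G": 0.000, "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186,
    "M": 0.221, "N": 0.134, "P": 0.131, "Q": 0.180, "R": 0.291,
    "S": 0.062, "T": 0.108, "V": 0.140, "W": 0.409, "Y": 0.298,
}

# SASA: solvent-accessible surface area (tripeptide reference, nm^2)
_SASA = {
    "A": 1.181, "C": 1.461, "D": 1.587, "E": 1.862, "F": 2.228,
    "G": 0.881, "H": 2.025, "I": 1.810, "K": 2.258, "L": 1.931,
    "M": 2.034, "N": 1.655, "P": 1.468, "Q": 1.932, "R": 2.560,
    "S": 1.298, "T": 1.525, "V": 1.645, "W": 2.663, "Y": 2.368,
}

# NCI: net charge index of side chains
_NET_CHARGE_INDEX = {
    "A": 0.007187, "C": -0.036610, "D": -0.023820, "E": 0.006802,
    "F": 0.037552, "G": 0.179052, "H": -0.010690, "I": 0.021631,
    "K": 0.017708, "L": 0.051672, "M": 0.002683, "N": 0.005392,
    "P": 0.239531, "Q": 0.049211, "R": 0.043587, "S": 0.004627,
    "T": 0.003352, "V": 0.057004, "W": 0.037977, "Y": 0.023599,
}

# side-chain mass (Da), used as the third PseAAC property
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

AC_PROPERTY_NAMES = ("H1", "H2", "VSC", "P1", "P2", "SASA", "NCI")
_AC_TABLES = (
    _HYDROPHOBICITY,
    _HYDROPHILICITY,
    _SIDE_CHAIN_VOLUME,
    _POLARITY,
    _POLARIZABILITY,
    _SASA,
    _NET_CHARGE_INDEX,
)

PSEAAC_PROPERTY_NAMES = ("H1", "H2", "mass")
_PSEAAC_TABLES = (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDE_CHAIN_MASS)


class PropertyTable:
    """Mapping amino acid -> vector of property values, optionally standardized.

    Standardization (population mean 0, variance 1 over the 20 standard amino
    acids, per column) is the default and the convention assumed throughout
    the encoders.
    """

    def __init__(self, tables, names, standardize: bool = True) -> None:
        mat = np.array(
            [[tab[aa] for tab in tables] for aa in STANDARD_AA], dtype=float
        )
        if standardize:
            mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
        self.matrix = mat  # shape (20, n_properties), rows in STANDARD_AA order
        self.names = tuple(names)
        self.standardized = standardize
        self._index = {aa: i for i, aa in enumerate(STANDARD_AA)}

    @property
    def n_properties(self) -> int:
        return self.matrix.shape[1]

    def profile(self, seq: str, policy: str = "impute") -> np.ndarray:
        """Per-residue property matrix of shape (len(seq), n_properties).

        policy="impute": non-standard residues take the column mean (zero when
        standardized).  policy="strict": raise on the first non-standard
        residue, reporting its 1-based position.
        """
        col_mean = self.matrix.mean(axis=0)
        rows = np.empty((len(seq), self.n_properties), dtype=float)
        for i, aa in enumerate(seq):
            j = self._index.get(aa)
            if j is None:
                if policy == "strict":
                    raise ValueError(
                        f"non-standard residue {aa!r} at position {i + 1}"
                    )
                rows[i] = col_mean
            else:
                rows[i] = self.matrix[j]
        return rows


def ac_property_table(standardize: bool = True) -> PropertyTable:
    """The seven scales used by the autocovariance encoder."""
    return PropertyTable(_AC_TABLES, AC_PROPERTY_NAMES, standardize)


def pseaac_property_table(standardize: bool = True) -> PropertyTable:
    """Hydrophobicity, hydrophilicity and side-chain mass for PseAAC."""
    return PropertyTable(_PSEAAC_TABLES, PSEAAC_PROPERTY_NAMES, standardize)


# Seven-group partition of the amino-acid alphabet by dipole moment and
# side-chain volume; used by the conjoint-triad and local-descriptor encoders.
SEVEN_GROUPS: dict[str, int] = {}
for _g, _letters in enumerate(
    ("AGV", "C", "FILP", "MSTY", "HNQW", "KR", "DE"), start=1
):
    for _aa in _letters:
        SEVEN_GROUPS[_aa] = _g

# Most common resolutions of ambiguity codes, for the "impute" policy.
# B (Asp/Asn) and Z (Glu/Gln) resolve to the acidic group; U (selenocysteine)
# behaves like cysteine.  X/J/O have no dominant resolution and are dropped.
AMBIGUOUS_GROUP: dict[str, int] = {"B": 7, "Z": 7, "U": 2}
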