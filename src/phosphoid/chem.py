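"""Monoisotopic mass bookkeeping for peptides and their modifications.

All masses are monoisotopic daltons.  Residue masses are the standard
20-letter table; termini follow the usual convention of adding one water
per peptide.  Fragment ions are charged by proton addition.
"""

from __future__ import annotations

# Atomic monoisotopic masses (CODATA / IUPAC 2021 rounded to 1e-8 Da)
ATOMIC_MASS = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON = 1.0072765
WATER = 18.010565
AMMONIA = 17.026549
PHOSPHORIC_ACID = 97.976896   # H3PO4, the dominant neutral loss of phospho-S/T
PHOSPHO = 79.966331           # HPO3, mass added by phosphorylation
CARBAMIDOMETHYL = 57.021464   # C2H3NO, fixed modification on cysteine

# Monoisotopic residue masses of the 20 standard amino acids.
RESIDUE_MASS = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "W": 186.079313,
    "Y": 163.063329,
}

STANDARD_AA = frozenset(RESIDUE_MASS)

# Residues that can carry a variable phospho group in CID workflows
# (phosphotyrosine rarely produces a neutral loss and is excluded).
PHOSPHO_RESIDUES = frozenset("ST")


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of a molecular formula given as element counts."""
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element {exc}") from exc


def residue_sum(sequence: str) -> float:
    """Sum of residue monoisotopic masses, no termini, no modifications."""
    try:
        return sum(RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc} in {sequence!r}") from exc


def peptide_mass(sequence: str, n_phospho: int = 0, *, fixed_cam: bool = True) -> float:
    """Neutral monoisotopic mass of a peptide.

    Parameters
    ----------
    sequence
        Amino-acid string of standard residues.
    n_phospho
        Number of variable phospho groups carried (site-unresolved).
    fixed_cam
        Apply carbamidomethylation to every cysteine (fixed modification).

    Returns
    -------
    float
        Residue sum + one water + modification deltas, in Da.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    if n_phospho < 0:
        raise ValueError("n_phospho must be non-negative")
    mass = residue_sum(sequence) + WATER + PHOSPHO * n_phospho
    if fixed_cam:
        mass += CARBAMIDOMETHYL * sequence.count("C")
    return mass


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """m/z of an ion formed by adding ``charge`` protons to a neutral mass."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge
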