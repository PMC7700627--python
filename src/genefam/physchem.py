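"""Protein physicochemical profiling.

Implements the five ProtParam-style calculators used to characterize a
gene family — molecular weight, isoelectric point, GRAVY, aliphatic
index, instability index — plus the classification flags derived from
them: acidic (pI < 7.0) vs basic, unstable (II > 40) vs stable,
thermostable (AI > 65), and hydrophilic (GRAVY < 0) vs hydrophobic.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import DIWV  # Guruprasad et al. 1990 dipeptide weights

from .seqio import SequenceRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Average (isotopically averaged) residue masses in daltons, Expasy values.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa set as used by ProtParam (Bjellqvist et al. 1993).
PKA_SIDECHAIN_NEG = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_SIDECHAIN_POS = {"H": 5.98, "K": 10.0, "R": 12.0}
PKA_CTERM_DEFAULT = 3.55
PKA_CTERM = {"D": 4.55, "E": 4.75}
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44,
             "E": 7.7}

# Ikai (1980) aliphatic-index coefficients: relative side-chain volumes of
# Val and Ile/Leu versus Ala.
AI_COEF_VAL = 2.9
AI_COEF_ILE_LEU = 3.9


class NonStandardResidueError(ValueError):
    pass


def _residues(seq) -> str:
    if isinstance(seq, SequenceRecord):
        if seq.alphabet != "protein":
            raise ValueError(f"{seq.id!r}: expected a protein record")
        return seq.residues
    return str(seq).upper()


def _check_standard(residues: str, what: str) -> None:
    if not residues:
        raise ValueError(f"{what}: empty sequence")
    bad = [i + 1 for i, a in enumerate(residues) if a not in AVERAGE_RESIDUE_MASS]
    if bad:
        raise NonStandardResidueError(
            f"{what}: non-standard residues at positions {bad[:10]}"
        )


def molecular_weight(seq) -> float:
    """Average molecular weight in kilodaltons (residue masses + one water)."""
    residues = _residues(seq)
    _check_standard(residues, "molecular_weight")
    da = sum(AVERAGE_RESIDUE_MASS[a] for a in residues) + WATER_MASS
    return da / 1000.0


def charge_at_pH(residues: str, pH: float) -> float:
    """Net protein charge from the Henderson–Hasselbalch equation.

    Positive groups: N-terminus, His, Lys, Arg. Negative groups:
    C-terminus, Asp, Glu, Cys, Tyr. Strictly decreasing in pH.
    """
    pos = [PKA_NTERM.get(residues[0], PKA_NTERM_DEFAULT)]
    neg = [PKA_CTERM.get(residues[-1], PKA_CTERM_DEFAULT)]
    for a in residues:
        if a in PKA_SIDECHAIN_POS:
            pos.append(PKA_SIDECHAIN_POS[a])
        elif a in PKA_SIDECHAIN_NEG:
            neg.append(PKA_SIDECHAIN_NEG[a])
    charge = sum(1.0 / (1.0 + 10 ** (pH - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - pH)) for pka in neg)
    return charge


def isoelectric_point(seq, tol: float = 0.001) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The charge function always has a root in (0, 14): the N-terminus is
    protonated (positive) at pH 0 and the C-terminus deprotonated
    (negative) at pH 14.
    """
    residues = _residues(seq)
    _check_standard(residues, "isoelectric_point")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if charge_at_pH(residues, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(seq) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle value."""
    residues = _residues(seq)
    _check_standard(residues, "gravy")
    return sum(KYTE_DOOLITTLE[a] for a in residues) / len(residues)


def aliphatic_index(seq) -> float:
    """Ikai aliphatic index: X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)),
    with X the mole percent over the full sequence length."""
    residues = _residues(seq)
    _check_standard(residues, "aliphatic_index")
    n = len(residues)
    x = {a: 100.0 * residues.count(a) / n for a in "AVIL"}
    return x["A"] + AI_COEF_VAL * x["V"] + AI_COEF_ILE_LEU * (x["I"] + x["L"])


def instability_index(seq) -> float:
    """Guruprasad instability index: (10/L)·sum of dipeptide weights over
    the L−1 overlapping dipeptides. Dipeptides absent from the published
    table weight 1.0."""
    residues = _residues(seq)
    _check_standard(residues, "instability_index")
    if len(residues) < 2:
        raise ValueError("instability_index requires length >= 2")
    total = 0.0
    for a, b in zip(residues, residues[1:]):
        total += DIWV.get(a, {}).get(b, 1.0)
    return 10.0 * total / len(residues)


@dataclass
class PhyschemProfile:
    """One protein's row of a family characterization table."""

    gene_id: str
    length_aa: int
    mw_kda: float
    pi: float
    ai: float
    ii: float
    gravy: float
    charge_class: str        # "acidic" (pI < 7.0) | "basic"
    stability: str           # "unstable" (II > 40) | "stable"
    thermostable: bool       # AI > 65
    hydropathy_class: str    # "hydrophilic" (GRAVY < 0) | "hydrophobic"

    @property
    def flags(self) -> tuple[str, ...]:
        return (
            self.charge_class,
            self.stability,
            "thermostable" if self.thermostable else "not_thermostable",
            self.hydropathy_class,
        )


def classify(pi: float, ii: float, ai: float, gravy_value: float) -> dict:
    """Apply the family-characterization thresholds to computed values.

    Boundary handling: pI >= 7.0 is basic (acidic is strictly < 7.0);
    II = 40 exactly is stable; AI = 65 exactly is not thermostable
    (thermostability requires AI strictly greater than 65); GRAVY >= 0
    is hydrophobic.
    """
    return {
        "charge_class": "acidic" if pi < 7.0 else "basic",
        "stability": "unstable" if ii > 40.0 else "stable",
        "thermostable": ai > 65.0,
        "hydropathy_class": "hydrophilic" if gravy_value < 0.0 else "hydrophobic",
    }


def profile(seq) -> PhyschemProfile:
    """Aggregate all five calculators and classification flags."""
    residues = _residues(seq)
    gene_id = seq.id if isinstance(seq, SequenceRecord) else "seq"
    mw = molecular_weight(residues)
    pi = isoelectric_point(residues)
    ai = aliphatic_index(residues)
    ii = instability_index(residues)
    gr = gravy(residues)
    return PhyschemProfile(
        gene_id=gene_id, length_aa=len(residues), mw_kda=mw, pi=pi, ai=ai,
        ii=ii, gravy=gr, **classify(pi, ii, ai, gr),
    )
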