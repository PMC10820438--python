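"""Physicochemical descriptors: molecular weight, theoretical pI, GRAVY,
charged-residue counts and Kyte-Doolittle hydropathy profiles.

These re-implement the classic ProtParam-style computations so the
census report can profile candidate hydrophobins without a web service:
average-mass molecular weight, Bjellqvist-pKa isoelectric point found by
charge bisection, grand average of hydropathicity on the Kyte-Doolittle
scale, D+E / K+R charge tallies (histidine excluded by convention), and
sliding-window hydropathy profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "KYTE_DOOLITTLE",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "PkaTable",
    "PhyschemProfile",
    "molecular_weight",
    "gravy",
    "net_charge",
    "theoretical_pi",
    "charged_counts",
    "hydropathy_profile",
    "physchem_profile",
]

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic).
KYTE_DOOLITTLE: Dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Average residue masses (Da); protein MW = sum + one water.
AVERAGE_RESIDUE_MASS: Dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

WATER_MASS = 18.01524


def _validate(seq: str, op: str) -> None:
    if not seq:
        raise ValueError(f"{op}: empty sequence")
    bad = set(seq) - set(KYTE_DOOLITTLE)
    if bad:
        raise ValueError(f"{op}: non-canonical residue(s) {sorted(bad)}")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    _validate(seq, "molecular_weight")
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def gravy(seq: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value."""
    _validate(seq, "gravy")
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


@dataclass(frozen=True)
class PkaTable:
    """Bjellqvist-style pKa set for the charge model behind the pI.

    Side-chain pKas for the seven ionizable residues, a flat C-terminal
    pKa, and residue-specific N-terminal pKas with a default for the
    rest. All values must lie in (0, 14).
    """

    side_chain: Dict[str, float] = field(
        default_factory=lambda: {
            "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
            "H": 5.98, "K": 10.0, "R": 12.0,
        }
    )
    c_term: float = 3.55
    n_term_default: float = 7.5
    n_term_by_residue: Dict[str, float] = field(
        default_factory=lambda: {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
            "T": 6.82, "V": 7.44, "E": 7.7, "G": 7.5,
        }
    )

    def __post_init__(self) -> None:
        values = [*self.side_chain.values(), self.c_term, self.n_term_default,
                  *self.n_term_by_residue.values()]
        if any(not 0 < v < 14 for v in values):
            raise ValueError("pKa values must lie in (0, 14)")

    def n_term(self, first_residue: str) -> float:
        return self.n_term_by_residue.get(first_residue, self.n_term_default)


_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def net_charge(seq: str, ph: float, pka: Optional[PkaTable] = None) -> float:
    """Henderson-Hasselbalch net charge of ``seq`` at ``ph``.

    Strictly decreasing in pH, which guarantees a unique pI root.
    """
    _validate(seq, "net_charge")
    pka = pka or PkaTable()
    pos = 1.0 / (1.0 + 10 ** (ph - pka.n_term(seq[0])))
    for aa in _BASIC:
        n = seq.count(aa)
        if n:
            pos += n / (1.0 + 10 ** (ph - pka.side_chain[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka.c_term - ph))
    for aa in _ACIDIC:
        n = seq.count(aa)
        if n:
            neg += n / (1.0 + 10 ** (pka.side_chain[aa] - ph))
    return pos - neg


def theoretical_pi(
    seq: str, pka: Optional[PkaTable] = None, tol: float = 1e-4
) -> float:
    """pH at which the modeled net charge crosses zero, by bisection.

    The termini are always ionizable, so a root exists in (0, 14);
    bisection runs until ``|charge| < tol``.
    """
    _validate(seq, "theoretical_pi")
    pka = pka or PkaTable()
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = 0.5 * (lo + hi)
        q = net_charge(seq, ph, pka)
        if abs(q) < tol:
            break
        if q > 0:  # still net positive: pI is at higher pH
            lo = ph
        else:
            hi = ph
    return ph


def charged_counts(seq: str) -> Tuple[int, int]:
    """(negative, positive) residue counts: D+E and K+R; His excluded."""
    _validate(seq, "charged_counts")
    return seq.count("D") + seq.count("E"), seq.count("K") + seq.count("R")


def hydropathy_profile(
    seq: str, window: int = 9, scale: Optional[Dict[str, float]] = None
) -> np.ndarray:
    """Sliding unweighted-mean hydropathy; one value per window center.

    ``window`` must be odd and no longer than the sequence; the output
    has ``len(seq) - window + 1`` values.
    """
    _validate(seq, "hydropathy_profile")
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    scale = scale or KYTE_DOOLITTLE
    values = np.array([scale[aa] for aa in seq], dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    mw: float
    pi: float
    gravy: float
    n_negative: int
    n_positive: int
    hydropathy: np.ndarray = field(repr=False, compare=False)


def physchem_profile(
    protein_id: str,
    seq: str,
    window: int = 9,
    pka: Optional[PkaTable] = None,
) -> PhyschemProfile:
    """All descriptors for one sequence (profile window clipped for short
    sequences)."""
    neg, pos = charged_counts(seq)
    w = min(window, len(seq) if len(seq) % 2 else len(seq) - 1)
    return PhyschemProfile(
        protein_id=protein_id,
        length=len(seq),
        mw=molecular_weight(seq),
        pi=theoretical_pi(seq, pka),
        gravy=gravy(seq),
        n_negative=neg,
        n_positive=pos,
        hydropathy=hydropathy_profile(seq, w),
    )


def physchem_table(records: Sequence) -> "pd.DataFrame":
    """Descriptor table (one row per record, MW/pI to 2 decimals)."""
    import pandas as pd

    rows: List[dict] = []
    for rec in records:
        p = physchem_profile(rec.id, rec.sequence)
        rows.append(
            {
                "name": p.protein_id,
                "n_amino_acids": p.length,
                "molecular_weight_da": round(p.mw, 2),
                "theoretical_pi": round(p.pi, 2),
                "gravy": round(p.gravy, 3),
                "n_negative_charged": p.n_negative,
                "n_positive_charged": p.n_positive,
            }
        )
    return pd.DataFrame(rows)
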