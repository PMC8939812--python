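"""Average molecular weight and isoelectric point, ProtParam-compatible.

Molecular weight is the sum of average (isotope-abundance-weighted)
residue masses plus one water; the mass table is the ExPASy set.  The
isoelectric point is the pH at which the Henderson–Hasselbalch net
charge over all ionizable groups (side chains of D, E, H, C, Y, K, R
plus both termini) crosses zero, located by bisection on [0, 14].  The
pKa values are the Bjellqvist set used by the ExPASy ProtParam tool,
including its residue-specific N-terminal pKas; both tables can be
overridden per call.

Net charge is strictly decreasing in pH, so the root is unique and
bisection cannot stall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .seqio import SequenceRecord

#: ExPASy average residue (amino acid minus water) masses, Da
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: mean of the 20 standard residue masses, substituted for X/B/Z only
#: when ambiguity is explicitly allowed
MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)


@dataclass(frozen=True)
class PkaTable:
    """Bjellqvist pKa set as implemented by ExPASy ProtParam.

    ``n_terminus`` maps the first residue to its alpha-amino pKa and
    ``c_terminus`` the last residue to its alpha-carboxyl pKa (the
    Bjellqvist set shifts it for terminal D and E); residues absent
    from either map fall back to the generic default.
    """

    c_terminus_default: float = 3.55
    n_terminus_default: float = 7.5
    n_terminus: Mapping[str, float] = field(default_factory=lambda: {
        "A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36,
        "T": 6.82, "V": 7.44, "E": 7.70,
    })
    c_terminus: Mapping[str, float] = field(default_factory=lambda: {
        "D": 4.55, "E": 4.75,
    })
    acidic_side_chains: Mapping[str, float] = field(default_factory=lambda: {
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    })
    basic_side_chains: Mapping[str, float] = field(default_factory=lambda: {
        "H": 5.98, "K": 10.0, "R": 12.0,
    })

    def __post_init__(self):
        for v in (self.c_terminus_default, self.n_terminus_default,
                  *self.n_terminus.values(), *self.c_terminus.values(),
                  *self.acidic_side_chains.values(),
                  *self.basic_side_chains.values()):
            if not 0 < v < 14:
                raise ValueError(f"pKa {v} outside (0, 14)")


DEFAULT_PKA = PkaTable()

_AMBIGUOUS = set("XBZUO")


def _residues(sequence) -> str:
    if isinstance(sequence, SequenceRecord):
        return sequence.residues
    return str(sequence).upper()


def molecular_weight(sequence, mass_table: Mapping[str, float] | None = None,
                     allow_ambiguous: bool = False) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water.

    Ambiguous residues (X, B, Z, U, O) are a hard error unless
    ``allow_ambiguous`` is set, in which case the mean standard residue
    mass is substituted with a warning.
    """
    import warnings

    table = AVERAGE_RESIDUE_MASS if mass_table is None else mass_table
    seq = _residues(sequence)
    if not seq:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(seq, start=1):
        if aa in table:
            total += table[aa]
        elif aa in _AMBIGUOUS:
            if not allow_ambiguous:
                raise ValueError(
                    f"ambiguous residue {aa!r} at position {pos}; "
                    "pass allow_ambiguous=True to substitute a mean residue mass"
                )
            warnings.warn(
                f"substituting mean residue mass for {aa!r} at position {pos}",
                stacklevel=2,
            )
            total += MEAN_RESIDUE_MASS
        else:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    return total


def _ionizable_groups(seq: str, pka: PkaTable) -> list[tuple[float, int, int]]:
    """(pKa, count, sign) triples; sign +1 basic, -1 acidic."""
    groups = [
        (pka.n_terminus.get(seq[0], pka.n_terminus_default), 1, +1),
        (pka.c_terminus.get(seq[-1], pka.c_terminus_default), 1, -1),
    ]
    for aa, k in pka.basic_side_chains.items():
        c = seq.count(aa)
        if c:
            groups.append((k, c, +1))
    for aa, k in pka.acidic_side_chains.items():
        c = seq.count(aa)
        if c:
            groups.append((k, c, -1))
    return groups


def net_charge(sequence, pH: float, pka_table: PkaTable | None = None) -> float:
    """Henderson–Hasselbalch net charge at ``pH`` (termini included).

    Each basic group contributes ``1/(1+10^(pH-pKa))`` and each acidic
    group ``-1/(1+10^(pKa-pH))``.
    """
    pka = pka_table or DEFAULT_PKA
    seq = _residues(sequence)
    if not seq:
        raise ValueError("empty sequence")
    charge = 0.0
    for k, count, sign in _ionizable_groups(seq, pka):
        if sign > 0:
            charge += count / (1.0 + 10.0 ** (pH - k))
        else:
            charge -= count / (1.0 + 10.0 ** (k - pH))
    return charge


def isoelectric_point(sequence, pka_table: PkaTable | None = None,
                      tol: float = 0.001) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Every sequence carries both termini, so the charge runs from
    positive (low pH) to negative (high pH) and the root exists and is
    unique (the charge is strictly decreasing in pH).
    """
    pka = pka_table or DEFAULT_PKA
    seq = _residues(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _round_half_up(value: float, digits: int) -> Decimal:
    return Decimal(repr(value)).quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP)


def format_mw(mw_da: float, style: str = "obp") -> str:
    """Catalog display: integer Da for OBPs, kDa to 3 decimals for ORs."""
    if style == "obp":
        return str(int(_round_half_up(mw_da, 0)))
    if style == "or":
        return f"{_round_half_up(mw_da / 1000.0, 3).normalize():f}"
    raise ValueError(f"unknown display style {style!r}")


def format_pi(pi: float, style: str = "obp") -> str:
    """Catalog display: 1 decimal for OBPs, 2 decimals for ORs (half-up)."""
    if style == "obp":
        return f"{_round_half_up(pi, 1)}"
    if style == "or":
        return f"{_round_half_up(pi, 2).normalize():f}"
    raise ValueError(f"unknown display style {style!r}")


@dataclass
class PhyschemProfile:
    sequence_id: str
    mw_da: float
    pi: float

    def display(self, style: str = "obp") -> tuple[str, str]:
        return format_mw(self.mw_da, style), format_pi(self.pi, style)


def profile(sequence: SequenceRecord, pka_table: PkaTable | None = None,
            allow_ambiguous: bool = False) -> PhyschemProfile:
    return PhyschemProfile(
        sequence_id=sequence.id,
        mw_da=molecular_weight(sequence, allow_ambiguous=allow_ambiguous),
        pi=isoelectric_point(sequence, pka_table),
    )


class PhyschemProfiler(BaseEstimator, TransformerMixin):
    """Transformer mapping protein sequences to [MW (Da), pI] features.

    Stateless; ``fit`` validates parameters only.  Accepts strings or
    :class:`SequenceRecord` samples and returns an (n, 2) float array,
    composable inside scikit-learn pipelines.
    """

    def __init__(self, pka_table: PkaTable | None = None,
                 allow_ambiguous: bool = False, pi_tol: float = 0.001):
        self.pka_table = pka_table
        self.allow_ambiguous = allow_ambiguous
        self.pi_tol = pi_tol

    def fit(self, X, y=None):
        self.pka_table_ = self.pka_table or DEFAULT_PKA
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "pka_table_"):
            self.fit(X)
        rows = []
        for x in X:
            seq = _residues(x)
            rows.append([
                molecular_weight(seq, allow_ambiguous=self.allow_ambiguous),
                isoelectric_point(seq, self.pka_table_, tol=self.pi_tol),
            ])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.array(["mw_da", "pi"], dtype=object)


def profile_set(sequences: Iterable[SequenceRecord],
                pka_table: PkaTable | None = None,
                allow_ambiguous: bool = False) -> list[PhyschemProfile]:
    return [profile(s, pka_table, allow_ambiguous) for s in sequences]
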