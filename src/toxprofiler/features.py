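"""Per-protein sequence features and functional indicator flags.

The predictors of overexpression toxicity studied here are cheap sequence
properties: the count of positively charged residues (arginine + lysine),
the count of negatively charged residues (aspartate + glutamate), the
isoelectric point, the length, and the mean Kyte-Doolittle hydropathy
rescaled to [0, 1] — plus boolean membership flags for the functional
classes used downstream (transcription factor, regulatory, catalytic,
macromolecular complex).

The isoelectric point is the pH at which the protein's net charge,
summed over ionizable groups via Henderson-Hasselbalch occupancies,
is zero; it is found by bisection, which is exact up to the tolerance
because net charge is strictly decreasing in pH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import ProteinRecord

POSITIVE_RESIDUES = "RK"
NEGATIVE_RESIDUES = "DE"

#: Kyte-Doolittle hydropathy scale, spanning -4.5 (Arg) to +4.5 (Ile).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

STANDARD_RESIDUES = frozenset(KYTE_DOOLITTLE)
#: ambiguity/rare codes kept in sequences but outside every feature formula
AMBIGUOUS_RESIDUES = frozenset("BJXZUO")


@dataclass(frozen=True)
class PkaSet:
    """pKa values for the ionizable groups used in net-charge calculations.

    ``side_chains`` maps residue -> (pKa, sign) with sign +1 for basic
    groups (K, R, H) and -1 for acidic ones (D, E, C, Y).  The termini are
    always included, which guarantees at least one group of each sign and
    hence a unique isoelectric point for any sequence.
    """

    n_terminus: float
    c_terminus: float
    side_chains: Mapping[str, tuple[float, int]]

    def __post_init__(self) -> None:
        for val in (self.n_terminus, self.c_terminus):
            if not 0 < val < 14:
                raise ValueError("terminal pKa values must lie in (0, 14)")
        for res, (pka, sign) in self.side_chains.items():
            if not 0 < pka < 14 or sign not in (-1, 1):
                raise ValueError(f"bad side-chain entry for {res}")


#: named pKa conventions selectable via config
PKA_SETS: dict[str, PkaSet] = {
    "emboss": PkaSet(
        n_terminus=8.6,
        c_terminus=3.6,
        side_chains={
            "K": (10.8, +1), "R": (12.5, +1), "H": (6.5, +1),
            "D": (3.9, -1), "E": (4.1, -1), "C": (8.5, -1), "Y": (10.1, -1),
        },
    ),
    "sillero": PkaSet(
        n_terminus=8.2,
        c_terminus=3.2,
        side_chains={
            "K": (10.4, +1), "R": (12.0, +1), "H": (6.4, +1),
            "D": (4.0, -1), "E": (4.5, -1), "C": (9.0, -1), "Y": (10.0, -1),
        },
    ),
}

DEFAULT_PKA_SET = "emboss"


@dataclass
class FeatureVector:
    """The per-protein predictors, one row of the feature table."""

    id: str
    positive_count: int
    negative_count: int
    pI: float
    length: int
    hydropathy: float
    is_tf: bool = False
    is_regulatory: bool = False
    is_catalytic: bool = False
    in_complex: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.positive_count <= self.length:
            raise ValueError("positive_count out of range")
        if not 0 <= self.negative_count <= self.length:
            raise ValueError("negative_count out of range")
        if not 0 < self.pI < 14:
            raise ValueError("pI out of range")
        if not 0 <= self.hydropathy <= 1:
            raise ValueError("hydropathy out of range")


def count_charged(sequence: str) -> tuple[int, int]:
    """Counts of positively (R+K) and negatively (D+E) charged residues.

    Histidine is not counted as positive: the charge features follow the
    arginine/lysine definition, while pI keeps H as an ionizable group.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pos = sum(sequence.count(r) for r in POSITIVE_RESIDUES)
    neg = sum(sequence.count(r) for r in NEGATIVE_RESIDUES)
    return pos, neg


def net_charge(sequence: str, pH: float, pka: PkaSet | None = None) -> float:
    """Signed net charge at a given pH (elementary-charge units).

    Each basic group contributes ``1 / (1 + 10**(pH - pKa))`` and each
    acidic group ``-1 / (1 + 10**(pKa - pH))``; both termini are always
    included.  Ambiguity codes carry no ionizable group.
    """
    if pka is None:
        pka = PKA_SETS[DEFAULT_PKA_SET]
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for res, (pk, sign) in pka.side_chains.items():
        n = sequence.count(res)
        if not n:
            continue
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (pH - pk))
        else:
            charge -= n / (1.0 + 10.0 ** (pk - pH))
    return charge


def compute_pI(sequence: str, pka: PkaSet | None = None, tol: float = 1e-3) -> float:
    """Isoelectric point by bisection on [0, 14] to within ``tol`` pH units.

    net_charge is strictly decreasing in pH and the termini force
    ``net_charge(0) > 0 > net_charge(14)``, so the zero crossing exists and
    is unique.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if pka is None:
        pka = PKA_SETS[DEFAULT_PKA_SET]
    lo, hi = 0.0, 14.0
    for _ in range(100):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mean_hydropathy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy rescaled to [0, 1].

    Each residue value v is mapped to ``(v + 4.5) / 9`` and averaged over
    standard residues; ambiguity codes are excluded from both numerator and
    denominator.
    """
    vals = [KYTE_DOOLITTLE[r] for r in sequence if r in KYTE_DOOLITTLE]
    if not vals:
        raise ValueError("sequence has no standard residues")
    return float(np.mean([(v + 4.5) / 9.0 for v in vals]))


@dataclass
class ClassConfig:
    """Identifiers of the functional classes mapped onto indicator flags."""

    tf_class_id: str = "GO:0001071"
    regulatory_class_id: str = "GO:0050794"
    catalytic_class_id: str = "GO:0003824"
    complex_class_id: str = "GO:0032991"
    #: drop TFs from the regulatory flag (regulatory-excluding-TF analyses)
    exclude_tf_from_regulatory: bool = False


def featurize(
    record: ProteinRecord,
    classes: ClassConfig | None = None,
    pka: PkaSet | None = None,
) -> FeatureVector:
    """Compute the full feature vector for one protein record."""
    if classes is None:
        classes = ClassConfig()
    pos, neg = count_charged(record.sequence)
    is_tf = classes.tf_class_id in record.go_classes
    is_reg = classes.regulatory_class_id in record.go_classes
    if classes.exclude_tf_from_regulatory and is_tf:
        is_reg = False
    return FeatureVector(
        id=record.id,
        positive_count=pos,
        negative_count=neg,
        pI=compute_pI(record.sequence, pka),
        length=len(record.sequence),
        hydropathy=mean_hydropathy(record.sequence),
        is_tf=is_tf,
        is_regulatory=is_reg,
        is_catalytic=classes.catalytic_class_id in record.go_classes,
        in_complex=classes.complex_class_id in record.go_classes,
    )


FEATURE_COLUMNS = [
    "positive_count",
    "negative_count",
    "pI",
    "length",
    "hydropathy",
    "is_tf",
    "is_regulatory",
    "is_catalytic",
    "in_complex",
]


def featurize_all(
    records: Sequence[ProteinRecord],
    classes: ClassConfig | None = None,
    pka: PkaSet | None = None,
) -> pd.DataFrame:
    """Feature table (one row per record, indexed by id)."""
    rows = [featurize(r, classes, pka) for r in records]
    df = pd.DataFrame(
        [{c: getattr(v, c) for c in FEATURE_COLUMNS} for v in rows],
        index=[v.id for v in rows],
    )
    df.index.name = "id"
    return df


class SequenceFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer from protein records to the feature table.

    Parameters
    ----------
    pka_set : str
        Name of the pKa convention used for pI (``"emboss"`` or
        ``"sillero"``).
    tf_class_id, regulatory_class_id, catalytic_class_id, complex_class_id : str
        Class identifiers matched against each record's class memberships.
    exclude_tf_from_regulatory : bool
        If True, the regulatory flag is switched off for transcription
        factors, for regulatory-excluding-TF analyses.
    """

    def __init__(
        self,
        pka_set: str = DEFAULT_PKA_SET,
        tf_class_id: str = "GO:0001071",
        regulatory_class_id: str = "GO:0050794",
        catalytic_class_id: str = "GO:0003824",
        complex_class_id: str = "GO:0032991",
        exclude_tf_from_regulatory: bool = False,
    ):
        self.pka_set = pka_set
        self.tf_class_id = tf_class_id
        self.regulatory_class_id = regulatory_class_id
        self.catalytic_class_id = catalytic_class_id
        self.complex_class_id = complex_class_id
        self.exclude_tf_from_regulatory = exclude_tf_from_regulatory

    def fit(self, X: Sequence[ProteinRecord], y=None):  # noqa: D102 - stateless
        if self.pka_set not in PKA_SETS:
            raise ValueError(f"unknown pka_set {self.pka_set!r}")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> pd.DataFrame:
        self.fit(X)
        classes = ClassConfig(
            tf_class_id=self.tf_class_id,
            regulatory_class_id=self.regulatory_class_id,
            catalytic_class_id=self.catalytic_class_id,
            complex_class_id=self.complex_class_id,
            exclude_tf_from_regulatory=self.exclude_tf_from_regulatory,
        )
        return featurize_all(X, classes, PKA_SETS[self.pka_set])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_COLUMNS, dtype=object)
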