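"""Reading screen data and building analysis cohorts.

An overexpression screen classifies every clone of an E. coli ORF library
into one of three growth categories and one of three GFP-fluorescence
categories after induction.  A protein is called *toxic* when its clone
shows essentially no growth and no fluorescence — the combination in which
even a small amount of expressed protein arrests the host.  This module
parses the sequence (FASTA) and annotation (TSV) inputs, applies that label
rule, and carves out the analysis cohorts: the full clone set, the
cytoplasmic subset (secretory proteins excluded) and its secretory
complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)


class GrowthClass(str, Enum):
    ALMOST_NO_GROWTH = "ALMOST_NO_GROWTH"
    SLOW_GROWTH = "SLOW_GROWTH"
    NORMAL_GROWTH = "NORMAL_GROWTH"
    UNKNOWN = "UNKNOWN"


class FluorescenceClass(str, Enum):
    HIGH_FLUORESCENCE = "HIGH_FLUORESCENCE"
    FLUORESCENCE = "FLUORESCENCE"
    NO_FLUORESCENCE = "NO_FLUORESCENCE"
    UNKNOWN = "UNKNOWN"


class Localization(str, Enum):
    MEMBRANE = "MEMBRANE"
    OUTER_MEMBRANE = "OUTER_MEMBRANE"
    PERIPLASMIC_SPACE = "PERIPLASMIC_SPACE"
    OTHER = "OTHER"


#: localization tags that mark a protein as secretory (Sec-pathway substrate)
SECRETORY_TAGS = frozenset(
    {Localization.MEMBRANE, Localization.OUTER_MEMBRANE, Localization.PERIPLASMIC_SPACE}
)

_GROWTH_ALIASES = {
    "almost no growth": GrowthClass.ALMOST_NO_GROWTH,
    "almost_no_growth": GrowthClass.ALMOST_NO_GROWTH,
    "slow growth": GrowthClass.SLOW_GROWTH,
    "slow_growth": GrowthClass.SLOW_GROWTH,
    "normal growth": GrowthClass.NORMAL_GROWTH,
    "normal_growth": GrowthClass.NORMAL_GROWTH,
    "unknown": GrowthClass.UNKNOWN,
    "": GrowthClass.UNKNOWN,
}

_FLUOR_ALIASES = {
    "high fluorescence": FluorescenceClass.HIGH_FLUORESCENCE,
    "high_fluorescence": FluorescenceClass.HIGH_FLUORESCENCE,
    "fluorescence": FluorescenceClass.FLUORESCENCE,
    "no fluorescence": FluorescenceClass.NO_FLUORESCENCE,
    "no_fluorescence": FluorescenceClass.NO_FLUORESCENCE,
    "unknown": FluorescenceClass.UNKNOWN,
    "": FluorescenceClass.UNKNOWN,
}

_LOC_ALIASES = {
    "membrane": Localization.MEMBRANE,
    "inner membrane": Localization.MEMBRANE,
    "inner_membrane": Localization.MEMBRANE,
    "outer membrane": Localization.OUTER_MEMBRANE,
    "outer_membrane": Localization.OUTER_MEMBRANE,
    "periplasmic space": Localization.PERIPLASMIC_SPACE,
    "periplasmic_space": Localization.PERIPLASMIC_SPACE,
    "periplasm": Localization.PERIPLASMIC_SPACE,
    "other": Localization.OTHER,
    "cytoplasm": Localization.OTHER,
}


@dataclass
class ProteinRecord:
    """One protein of the screen: sequence plus screen/annotation fields."""

    id: str
    sequence: str
    growth_class: GrowthClass = GrowthClass.UNKNOWN
    fluorescence_class: FluorescenceClass = FluorescenceClass.UNKNOWN
    localization: frozenset[Localization] = field(default_factory=frozenset)
    tm_count: int = 0
    go_classes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.tm_count < 0:
            raise ValueError(f"record {self.id!r}: tm_count must be >= 0")

    @property
    def is_secretory(self) -> bool:
        return bool(self.localization & SECRETORY_TAGS)


@dataclass
class LabeledCohort:
    """A set of records with a per-record binary toxicity flag."""

    records: list[ProteinRecord]
    toxic_flags: np.ndarray
    cohort_name: str

    def __post_init__(self) -> None:
        self.toxic_flags = np.asarray(self.toxic_flags, dtype=bool)
        if len(self.records) != len(self.toxic_flags):
            raise ValueError("toxic_flags must align with records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_toxic(self) -> int:
        return int(self.toxic_flags.sum())

    @property
    def percent_toxic(self) -> float:
        return 100.0 * self.n_toxic / len(self) if len(self) else float("nan")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs in file order.

    Sequences are uppercased and trailing stop characters (``*``) stripped;
    the id is the first whitespace-delimited token of the header.  Duplicate
    ids and empty sequences raise ``ValueError``.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def _parse_growth(value: str, row: object) -> GrowthClass:
    key = str(value).strip().lower()
    try:
        return _GROWTH_ALIASES[key]
    except KeyError:
        raise ValueError(f"row {row!r}: unrecognized growth category {value!r}") from None


def _parse_fluor(value: str, row: object) -> FluorescenceClass:
    key = str(value).strip().lower()
    try:
        return _FLUOR_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"row {row!r}: unrecognized fluorescence category {value!r}"
        ) from None


def _parse_localization(value: str, row: object) -> frozenset[Localization]:
    tags: set[Localization] = set()
    for part in str(value).split(";"):
        part = part.strip().lower()
        if not part:
            continue
        try:
            tags.add(_LOC_ALIASES[part])
        except KeyError:
            raise ValueError(
                f"row {row!r}: unrecognized localization tag {part!r}"
            ) from None
    return frozenset(tags)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-protein annotation TSV into a table keyed by ``id``.

    Required columns: ``id``, ``growth_class``, ``fluorescence_class``.
    Optional: ``localization`` (semicolon-separated tags), ``tm_count``,
    ``go_classes`` (semicolon-separated identifiers).  Category strings are
    matched case-insensitively; "inner membrane" maps to the MEMBRANE tag.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "growth_class", "fluorescence_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")

    out = pd.DataFrame(index=df["id"])
    out.index.name = "id"
    out["growth_class"] = [
        _parse_growth(v, i) for i, v in zip(df["id"], df["growth_class"])
    ]
    out["fluorescence_class"] = [
        _parse_fluor(v, i) for i, v in zip(df["id"], df["fluorescence_class"])
    ]
    if "localization" in df.columns:
        out["localization"] = [
            _parse_localization(v, i) for i, v in zip(df["id"], df["localization"])
        ]
    else:
        out["localization"] = [frozenset()] * len(df)
    if "tm_count" in df.columns:
        out["tm_count"] = [int(v) if str(v).strip() else 0 for v in df["tm_count"]]
    else:
        out["tm_count"] = 0
    if "go_classes" in df.columns:
        out["go_classes"] = [
            frozenset(p.strip() for p in str(v).split(";") if p.strip())
            for v in df["go_classes"]
        ]
    else:
        out["go_classes"] = [frozenset()] * len(df)
    return out


def parse_tmhmm(lines: Iterable[str]) -> dict[str, int]:
    """Parse TMHMM short-format output lines into ``{id: predicted-helix-count}``.

    Each line looks like ``<id>\\tlen=..\\t..\\tPredHel=<k>\\t..``.
    """
    counts: dict[str, int] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        pred = [f for f in fields if f.startswith("PredHel=")]
        if not pred:
            continue
        counts[fields[0]] = int(pred[0].split("=", 1)[1])
    return counts


def build_records(
    sequences: Sequence[tuple[str, str]], annotations: pd.DataFrame
) -> list[ProteinRecord]:
    """Join sequences with annotation rows (inner join on id, FASTA order)."""
    records = []
    for pid, seq in sequences:
        if pid not in annotations.index:
            logger.info("no annotation for %s; skipped", pid)
            continue
        row = annotations.loc[pid]
        records.append(
            ProteinRecord(
                id=pid,
                sequence=seq,
                growth_class=row["growth_class"],
                fluorescence_class=row["fluorescence_class"],
                localization=row["localization"],
                tm_count=int(row["tm_count"]),
                go_classes=row["go_classes"],
            )
        )
    return records


def label_toxicity(
    growth_class: GrowthClass, fluorescence_class: FluorescenceClass
) -> bool:
    """Binary toxicity label for one clone.

    Toxic means the clone showed essentially no growth *and* no GFP
    fluorescence on induction; every other combination of the nine
    growth x fluorescence cells is non-toxic.  UNKNOWN categories are a
    caller error — such records are excluded upstream, not labeled.
    """
    if growth_class is GrowthClass.UNKNOWN or fluorescence_class is FluorescenceClass.UNKNOWN:
        raise ValueError("cannot label a record with UNKNOWN screen category")
    return (
        growth_class is GrowthClass.ALMOST_NO_GROWTH
        and fluorescence_class is FluorescenceClass.NO_FLUORESCENCE
    )


def build_cohort(records: Sequence[ProteinRecord], name: str = "ALL") -> LabeledCohort:
    """Label all classifiable records; drop (and count) UNKNOWN-category ones."""
    kept: list[ProteinRecord] = []
    flags: list[bool] = []
    dropped = 0
    for r in records:
        if (
            r.growth_class is GrowthClass.UNKNOWN
            or r.fluorescence_class is FluorescenceClass.UNKNOWN
        ):
            dropped += 1
            continue
        kept.append(r)
        flags.append(label_toxicity(r.growth_class, r.fluorescence_class))
    if dropped:
        logger.info("dropped %d records with UNKNOWN screen categories", dropped)
    cohort = LabeledCohort(kept, np.asarray(flags, dtype=bool), name)
    logger.info(
        "cohort %s: n=%d, toxic=%d (%.1f%%)",
        name,
        len(cohort),
        cohort.n_toxic,
        cohort.percent_toxic,
    )
    return cohort


def _is_cytoplasmic(record: ProteinRecord, mode: str) -> bool:
    if record.localization & SECRETORY_TAGS:
        return False
    if mode == "localization_or_tm":
        return record.tm_count == 0
    if mode == "localization_only":
        return True
    raise ValueError(f"unknown cytoplasmic filter mode {mode!r}")


def filter_cytoplasmic(
    records: Sequence[ProteinRecord], mode: str = "localization_or_tm"
) -> LabeledCohort:
    """The cytoplasmic cohort: secretory proteins excluded.

    Secretory proteins (membrane, outer-membrane and periplasmic) are
    excluded because their extreme toxicity plausibly runs through
    saturation of the Sec translocation machinery rather than the
    cytoplasmic mechanism under study.  ``mode`` controls whether proteins
    with predicted trans-membrane segments but no secretory localization tag
    are also dropped (``localization_or_tm``, the default) or kept
    (``localization_only``).
    """
    cyto = [r for r in records if _is_cytoplasmic(r, mode)]
    return build_cohort(cyto, name="CYTOPLASMIC")


def filter_secretory(
    records: Sequence[ProteinRecord], mode: str = "localization_or_tm"
) -> LabeledCohort:
    """The complement of the cytoplasmic cohort."""
    sec = [r for r in records if not _is_cytoplasmic(r, mode)]
    return build_cohort(sec, name="SECRETORY")


def stratify_by_tm(
    records: Sequence[ProteinRecord], toxic_flags: Sequence[bool]
) -> pd.DataFrame:
    """Percent toxic per trans-membrane-segment stratum {0, 1, >=2}.

    Empty strata are reported with n=0 and NaN percentage.
    """
    flags = np.asarray(toxic_flags, dtype=bool)
    if len(records) != len(flags):
        raise ValueError("toxic_flags must align with records")
    rows = []
    for name, pred in (
        ("0", lambda t: t == 0),
        ("1", lambda t: t == 1),
        (">=2", lambda t: t >= 2),
    ):
        mask = np.array([pred(r.tm_count) for r in records], dtype=bool)
        n = int(mask.sum())
        pct = 100.0 * flags[mask].sum() / n if n else float("nan")
        rows.append({"stratum": name, "n": n, "percent_toxic": pct})
    return pd.DataFrame(rows)


def cohort_summary(cohort: LabeledCohort) -> dict:
    """Counts per growth x fluorescence cell plus derived screen percentages.

    ``growth_inhibited_percent`` is the share of clones in either
    growth-inhibited category (almost-no-growth + slow-growth).
    """
    n = len(cohort)
    cells: dict[str, int] = {}
    growth_counts: dict[str, int] = {}
    for r in cohort.records:
        key = f"{r.growth_class.value}|{r.fluorescence_class.value}"
        cells[key] = cells.get(key, 0) + 1
        growth_counts[r.growth_class.value] = growth_counts.get(r.growth_class.value, 0) + 1
    growth_pct = {k: 100.0 * v / n for k, v in growth_counts.items()} if n else {}
    inhibited = sum(
        growth_pct.get(g.value, 0.0)
        for g in (GrowthClass.ALMOST_NO_GROWTH, GrowthClass.SLOW_GROWTH)
    )
    return {
        "cohort_name": cohort.cohort_name,
        "n": n,
        "n_toxic": cohort.n_toxic,
        "percent_toxic": cohort.percent_toxic,
        "cells": cells,
        "growth_percent": growth_pct,
        "growth_inhibited_percent": inhibited,
    }
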