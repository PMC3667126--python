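"""Synthetic proteome + overexpression screen with known ground truth.

The generator emulates the statistical landscape the analysis assumes:
i.i.d. sequences drawn from an E. coli-like residue composition with
log-normal lengths, functional-class memberships drawn per configurable
fractions (most transcription factors also carrying the regulatory class),
a secretory subpopulation with localization tags and trans-membrane counts,
and a binary toxicity label drawn from a logistic model on the *realized*
sequence features — so the measurement chain (sequence -> features ->
statistics) is exercised end to end, not short-circuited through latent
variables.  Screen categories are back-filled so the label rule recovers
the drawn labels exactly.

Every record of what went into each label is kept in a ground-truth table,
making the generator usable as an oracle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    FluorescenceClass,
    GrowthClass,
    Localization,
    ProteinRecord,
)
from .features import ClassConfig, compute_pI, count_charged

#: amino-acid letters in a fixed order for the frequency vector
RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: E. coli-like proteome residue composition (normalized at use)
ECOLI_FREQUENCIES: dict[str, float] = {
    "A": 0.095, "C": 0.012, "D": 0.051, "E": 0.057, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.044, "L": 0.105,
    "M": 0.028, "N": 0.040, "P": 0.044, "Q": 0.044, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.070, "W": 0.015, "Y": 0.028,
}

#: functional-class names -> emitted class identifiers
CLASS_IDS: dict[str, str] = {
    "TF": ClassConfig.tf_class_id,
    "REGULATORY": ClassConfig.regulatory_class_id,
    "CATALYTIC": ClassConfig.catalytic_class_id,
    "COMPLEX": ClassConfig.complex_class_id,
}


@dataclass
class ToxicityCoefficients:
    """Logistic-model coefficients generating the toxicity probability.

    logit p = intercept + b_pos*positive_count + b_len*length
              + b_pi_quad*(pI - 7)^2 + b_tf*TF + b_reg*REG + b_cat*CAT
              + b_sec*secretory
    """

    intercept: float = -3.22
    beta_positive: float = 0.03   # per R/K residue
    beta_length: float = 0.002    # per residue
    beta_pi_quad: float = 0.05    # per pH^2 from pH 7
    beta_tf: float = 1.2
    beta_regulatory: float = 0.8
    beta_catalytic: float = -0.6
    beta_secretory: float = 3.2

    @classmethod
    def null(cls, toxic_fraction: float = 0.4) -> "ToxicityCoefficients":
        """All effects zero; intercept set to logit(toxic_fraction)."""
        return cls(
            intercept=float(np.log(toxic_fraction / (1 - toxic_fraction))),
            beta_positive=0.0, beta_length=0.0, beta_pi_quad=0.0,
            beta_tf=0.0, beta_regulatory=0.0, beta_catalytic=0.0,
            beta_secretory=0.0,
        )


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults emulate the screen's
    landscape (~40% toxic overall, ~18% cytoplasmic, secretory >80%)."""

    n_proteins: int = 3956
    length_log_mean: float = 5.6   # log-residues; exp(5.6) ~ 270 aa
    length_log_sd: float = 0.45
    min_length: int = 30
    residue_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(ECOLI_FREQUENCIES)
    )
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "TF": 0.05,
            "REGULATORY": 0.15,
            "CATALYTIC": 0.50,
            "COMPLEX": 0.25,
            "GO:0032553": 0.12,   # inert decoy classes for the scan
            "GO:0006810": 0.10,
        }
    )
    tf_regulatory_share: float = 0.8
    secretory_fraction: float = 0.38
    tm_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.30, 1: 0.30, 2: 0.20, 3: 0.12, 4: 0.08}
    )
    coefficients: ToxicityCoefficients = field(default_factory=ToxicityCoefficients)
    #: (growth, fluorescence, weight) cells back-filled for non-toxic labels
    nontoxic_cell_mix: tuple[tuple[str, str, float], ...] = (
        ("SLOW_GROWTH", "FLUORESCENCE", 0.60),
        ("NORMAL_GROWTH", "HIGH_FLUORESCENCE", 0.25),
        ("ALMOST_NO_GROWTH", "FLUORESCENCE", 0.15),
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        freq = np.array([self.residue_frequencies[r] for r in RESIDUE_ORDER])
        if (freq < 0).any() or freq.sum() <= 0:
            raise ValueError("residue_frequencies must be non-negative, non-zero")
        for name, p in self.class_fractions.items():
            if not 0 <= p <= 1:
                raise ValueError(f"class fraction {name} outside [0,1]")
        if not 0 <= self.secretory_fraction <= 1:
            raise ValueError("secretory_fraction outside [0,1]")
        tm_p = np.array(list(self.tm_count_distribution.values()), dtype=float)
        if (tm_p < 0).any() or abs(tm_p.sum() - 1) > 1e-9:
            raise ValueError("tm_count_distribution must be a probability map")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nontoxic_cell_mix"] = [list(c) for c in self.nontoxic_cell_mix]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "coefficients" in d and isinstance(d["coefficients"], dict):
            d["coefficients"] = ToxicityCoefficients(**d["coefficients"])
        if "tm_count_distribution" in d:
            d["tm_count_distribution"] = {
                int(k): float(v) for k, v in d["tm_count_distribution"].items()
            }
        if "nontoxic_cell_mix" in d:
            d["nontoxic_cell_mix"] = tuple(
                (str(g), str(f), float(w)) for g, f, w in d["nontoxic_cell_mix"]
            )
        return cls(**d)


# fixed offsets carving independent streams out of the master seed
_STREAMS = {
    "lengths": 1, "sequences": 2, "classes": 3, "secretory": 4,
    "tm": 5, "labels": 6, "backfill": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(seed + _STREAMS[stream])


def generate_sequence(
    length: int, residue_frequencies: dict[str, float], rng: np.random.Generator
) -> str:
    """An i.i.d. residue string of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    freq = np.array([residue_frequencies[r] for r in RESIDUE_ORDER], dtype=float)
    freq = freq / freq.sum()
    letters = rng.choice(len(RESIDUE_ORDER), size=length, p=freq)
    return "".join(RESIDUE_ORDER[i] for i in letters)


def generate_proteome(config: GeneratorConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Draw a full synthetic proteome plus its ground-truth table.

    Returns ``(records, truth)`` where ``truth`` holds, per protein, the
    features used at label generation, the logistic toxicity probability
    and the drawn label.
    """
    config.validate()
    n = config.n_proteins
    seed = config.seed

    lengths = np.exp(
        _rng(seed, "lengths").normal(config.length_log_mean, config.length_log_sd, n)
    )
    lengths = np.maximum(np.rint(lengths).astype(int), config.min_length)

    seq_rng = _rng(seed, "sequences")
    sequences = [
        generate_sequence(int(L), config.residue_frequencies, seq_rng) for L in lengths
    ]

    class_rng = _rng(seed, "classes")
    class_names = list(config.class_fractions)
    membership = {
        name: class_rng.random(n) < frac
        for name, frac in config.class_fractions.items()
    }
    # most TFs also carry the regulatory class
    if "TF" in membership and "REGULATORY" in membership:
        tf_reg = class_rng.random(n) < config.tf_regulatory_share
        membership["REGULATORY"] = membership["REGULATORY"] | (
            membership["TF"] & tf_reg
        )

    secretory = _rng(seed, "secretory").random(n) < config.secretory_fraction
    tm_rng = _rng(seed, "tm")
    tm_values = np.array(list(config.tm_count_distribution), dtype=int)
    tm_probs = np.array(list(config.tm_count_distribution.values()), dtype=float)
    tm_counts = np.where(
        secretory, tm_rng.choice(tm_values, size=n, p=tm_probs), 0
    )
    loc_choice = tm_rng.random(n)  # periplasmic vs outer membrane for tm=0

    c = config.coefficients
    rows = []
    label_rng = _rng(seed, "labels")
    backfill_rng = _rng(seed, "backfill")
    mix_w = np.array([w for _, _, w in config.nontoxic_cell_mix], dtype=float)
    mix_w = mix_w / mix_w.sum()
    records: list[ProteinRecord] = []
    for i in range(n):
        seq = sequences[i]
        pos, neg = count_charged(seq)
        pi = compute_pI(seq)
        is_tf = bool(membership.get("TF", np.zeros(n, bool))[i])
        is_reg = bool(membership.get("REGULATORY", np.zeros(n, bool))[i])
        is_cat = bool(membership.get("CATALYTIC", np.zeros(n, bool))[i])
        logit = (
            c.intercept
            + c.beta_positive * pos
            + c.beta_length * len(seq)
            + c.beta_pi_quad * (pi - 7.0) ** 2
            + c.beta_tf * is_tf
            + c.beta_regulatory * is_reg
            + c.beta_catalytic * is_cat
            + c.beta_secretory * bool(secretory[i])
        )
        p_toxic = 1.0 / (1.0 + np.exp(-logit))
        toxic = bool(label_rng.random() < p_toxic)

        if toxic:
            growth, fluor = GrowthClass.ALMOST_NO_GROWTH, FluorescenceClass.NO_FLUORESCENCE
        else:
            cell = config.nontoxic_cell_mix[
                int(backfill_rng.choice(len(mix_w), p=mix_w))
            ]
            growth, fluor = GrowthClass[cell[0]], FluorescenceClass[cell[1]]

        if secretory[i]:
            if tm_counts[i] >= 1:
                loc = frozenset({Localization.MEMBRANE})
            elif loc_choice[i] < 0.5:
                loc = frozenset({Localization.PERIPLASMIC_SPACE})
            else:
                loc = frozenset({Localization.OUTER_MEMBRANE})
        else:
            loc = frozenset({Localization.OTHER})

        go = frozenset(
            CLASS_IDS.get(name, name)
            for name in class_names
            if membership[name][i]
        )
        pid = f"syn{i:05d}"
        records.append(
            ProteinRecord(
                id=pid,
                sequence=seq,
                growth_class=growth,
                fluorescence_class=fluor,
                localization=loc,
                tm_count=int(tm_counts[i]),
                go_classes=go,
            )
        )
        rows.append(
            {
                "id": pid,
                "length": len(seq),
                "positive_count": pos,
                "negative_count": neg,
                "pI": pi,
                "is_tf": is_tf,
                "is_regulatory": is_reg,
                "is_catalytic": is_cat,
                "in_complex": bool(membership.get("COMPLEX", np.zeros(n, bool))[i]),
                "is_secretory": bool(secretory[i]),
                "tm_count": int(tm_counts[i]),
                "p_toxic": float(p_toxic),
                "toxic": toxic,
            }
        )
    truth = pd.DataFrame(rows).set_index("id")
    return records, truth


def memberships_from_records(
    records: Sequence[ProteinRecord],
) -> dict[str, set[str]]:
    """Invert per-record class sets into ``{class_id: member ids}``."""
    out: dict[str, set[str]] = {}
    for r in records:
        for cid in r.go_classes:
            out.setdefault(cid, set()).add(r.id)
    return out


def recover_parameters(
    records: Sequence[ProteinRecord],
    truth: pd.DataFrame,
    seed: int = 0,
    n_repetitions: int = 10,
    n_estimators: int = 500,
    min_class_size: int = 200,
) -> dict:
    """Run the full analysis on generated data and summarize what it found.

    The report states, for each generating effect, whether the pipeline's
    observed direction agrees: toxic-vs-non-toxic medians and rank-sum p
    for positive count and length, the quadratic coefficient of the pI bin
    trend, Fisher odds ratios for the named functional classes (tested
    directly, independent of the scan's size floor), the secretory vs
    cytoplasmic toxicity gap, and the ablation AUCs.
    """
    from . import classify as _clf
    from . import stats as _st
    from .data_io import build_cohort as _build, filter_cytoplasmic as _cyto
    from .features import featurize_all

    all_cohort = _build(list(records), "ALL")
    cyto = _cyto(list(records))
    feats = featurize_all(cyto.records)
    flags = cyto.toxic_flags

    report: dict = {
        "n_all": len(all_cohort),
        "n_cytoplasmic": len(cyto),
        "percent_toxic_all": all_cohort.percent_toxic,
        "percent_toxic_cytoplasmic": cyto.percent_toxic,
    }
    sec_mask = np.array([r.is_secretory or r.tm_count > 0 for r in all_cohort.records])
    if sec_mask.any():
        report["percent_toxic_secretory"] = float(
            100.0 * all_cohort.toxic_flags[sec_mask].mean()
        )

    for name in ("positive_count", "length"):
        r = _st.rank_sum_test(feats.loc[flags, name], feats.loc[~flags, name])
        report[name] = {
            "toxic_median": r.group_summaries[0][1],
            "nontoxic_median": r.group_summaries[1][1],
            "p_value": r.p_value,
            "direction": r.effect_direction,
        }
    prof = _st.bin_toxicity_trend(
        feats["pI"], flags, k=20, fit_kind="QUADRATIC", feature_name="pI", seed=seed
    )
    report["pI_quadratic_coefficient"] = float(prof.fit_coefficients[0])

    memberships = memberships_from_records(cyto.records)
    ids = set(cyto.ids)
    n, n_toxic = len(cyto), cyto.n_toxic
    toxic_ids = {i for i, f in zip(cyto.ids, flags) if f}
    report["classes"] = {}
    for cname, cid in CLASS_IDS.items():
        members = memberships.get(cid, set()) & ids
        k = len(members)
        if k == 0 or k == n:
            continue
        k_tox = len(members & toxic_ids)
        tr = _st.fisher_2x2(
            [[k_tox, k - k_tox], [n_toxic - k_tox, (n - n_toxic) - (k - k_tox)]]
        )
        report["classes"][cname] = {
            "n_in_class": k,
            "percent_toxic": 100.0 * k_tox / k,
            "odds_ratio": tr.statistic,
            "p_value": tr.p_value,
        }
    report["enrichment_scan"] = [
        {
            "class_id": r.class_id,
            "percent_toxic": r.percent_toxic_in_class,
            "odds_ratio": r.odds_ratio,
            "p_value": r.p_value,
        }
        for r in _st.enrichment_scan(cyto, memberships, min_size=min_class_size)
    ]
    reports = _clf.ablation_compare(
        feats, flags, seed=seed,
        n_repetitions=n_repetitions, n_estimators=n_estimators,
    )
    report["auc"] = {r.feature_subset_name: r.mean_auc for r in reports}
    return report


def write_outputs(
    records: Sequence[ProteinRecord],
    truth: pd.DataFrame,
    fasta_path,
    annotations_path,
    truth_path=None,
) -> None:
    """Write the proteome as FASTA + annotation TSV (+ optional truth TSV)."""
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "growth_class": r.growth_class.value,
                "fluorescence_class": r.fluorescence_class.value,
                "localization": ";".join(sorted(t.value for t in r.localization)),
                "tm_count": r.tm_count,
                "go_classes": ";".join(sorted(r.go_classes)),
            }
        )
    pd.DataFrame(rows).to_csv(annotations_path, sep="\t", index=False)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", float_format="%.6g")
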