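"""End-to-end orchestration: cohorts -> features -> stats -> classification.

`run_pipeline` composes the whole analysis and writes a report bundle:
cohort summary with the growth x fluorescence cell counts and TM-stratum
toxicity table, the feature association tests, equal-frequency bin
profiles, the functional-class enrichment scan (including the
regulatory-excluding-TF re-run), and the balanced-resampling
classification reports.  Every random decision derives from the single
seed recorded in the report header, so a bundle is byte-reproducible from
its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as clf
from . import stats as st
from .data_io import (
    LabeledCohort,
    ProteinRecord,
    build_cohort,
    build_records,
    cohort_summary,
    filter_cytoplasmic,
    filter_secretory,
    parse_tmhmm,
    read_annotations,
    read_fasta,
    stratify_by_tm,
)
from .features import ClassConfig, SequenceFeaturizer
from .stats import class_minus_class, enrichment_scan, enrichment_table
from .synthetic import memberships_from_records

logger = logging.getLogger(__name__)

#: classes reported by name in the enrichment output
DEFAULT_CLASS_NAMES = {
    ClassConfig.tf_class_id: "nucleic acid binding transcription factor activity",
    ClassConfig.regulatory_class_id: "regulation of cellular processes",
    ClassConfig.catalytic_class_id: "catalytic activity",
    ClassConfig.complex_class_id: "macromolecular complex",
}

REGULATORY_MINUS_TF_ID = "REGULATORY_minus_TF"


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run; defaults follow the analysis protocol
    (20 bins, class-size floor 200, 10 balanced repetitions)."""

    fasta: str | None = None
    annotations: str | None = None
    tmhmm: str | None = None
    cohort: str = "CYTOPLASMIC"           # ALL | CYTOPLASMIC | SECRETORY
    cytoplasmic_filter: str = "localization_or_tm"
    min_class_size: int = 200
    bins: int = 20
    n_repetitions: int = 10
    n_estimators: int = 500
    holdout: str = "oob"
    pka_set: str = "emboss"
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        # outdir is a runtime sink, not an analysis parameter: leaving it out
        # keeps report bundles byte-identical across output locations
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return d


def load_records(config: PipelineConfig) -> list[ProteinRecord]:
    if not config.fasta or not config.annotations:
        raise ValueError("fasta and annotations paths are required")
    sequences = read_fasta(config.fasta)
    annotations = read_annotations(config.annotations)
    records = build_records(sequences, annotations)
    if config.tmhmm:
        with open(config.tmhmm) as fh:
            counts = parse_tmhmm(fh)
        for r in records:
            if r.id in counts:
                r.tm_count = counts[r.id]
    return records


def select_cohort(records: Sequence[ProteinRecord], config: PipelineConfig) -> LabeledCohort:
    name = config.cohort.upper()
    if name == "ALL":
        return build_cohort(records, "ALL")
    if name == "CYTOPLASMIC":
        return filter_cytoplasmic(records, config.cytoplasmic_filter)
    if name == "SECRETORY":
        return filter_secretory(records, config.cytoplasmic_filter)
    raise ValueError(f"unknown cohort {config.cohort!r}")


def _feature_tests(features: pd.DataFrame, flags: np.ndarray) -> pd.DataFrame:
    """Rank-sum tests (toxic vs non-toxic) on the continuous features plus
    the Welch t on hydropathy."""
    rows = []
    toxic = features.loc[flags]
    nontoxic = features.loc[~flags]
    for name in ("positive_count", "pI", "length"):
        r = st.rank_sum_test(toxic[name], nontoxic[name])
        rows.append(
            {
                "feature": name,
                "test": r.test_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "toxic_n": r.group_summaries[0][0],
                "toxic_center": r.group_summaries[0][1],
                "nontoxic_n": r.group_summaries[1][0],
                "nontoxic_center": r.group_summaries[1][1],
                "direction": r.effect_direction,
            }
        )
    r = st.two_sample_t(toxic["hydropathy"], nontoxic["hydropathy"])
    rows.append(
        {
            "feature": "hydropathy",
            "test": r.test_name,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "toxic_n": r.group_summaries[0][0],
            "toxic_center": r.group_summaries[0][1],
            "nontoxic_n": r.group_summaries[1][0],
            "nontoxic_center": r.group_summaries[1][1],
            "direction": r.effect_direction,
        }
    )
    return pd.DataFrame(rows)


def _bin_profiles(
    features: pd.DataFrame, flags: np.ndarray, k: int, seed: int
) -> tuple[pd.DataFrame, dict]:
    specs = [
        ("positive_count", "LINEAR"),
        ("length", "LINEAR"),
        ("pI", "QUADRATIC"),
    ]
    rows, fits = [], {}
    for name, kind in specs:
        prof = st.bin_toxicity_trend(
            features[name], flags, k=k, fit_kind=kind, feature_name=name, seed=seed
        )
        fits[name] = {
            "fit_kind": prof.fit_kind,
            "coefficients": [float(c) for c in prof.fit_coefficients],
        }
        for i in range(k):
            rows.append(
                {
                    "feature": name,
                    "bin": i,
                    "n": int(prof.bin_n[i]),
                    "mean_feature": float(prof.bin_mean_feature[i]),
                    "percent_toxic": float(prof.bin_percent_toxic[i]),
                }
            )
    return pd.DataFrame(rows), fits


def _enrichment(
    cohort: LabeledCohort, min_size: int
) -> pd.DataFrame:
    memberships = memberships_from_records(cohort.records)
    tf_id, reg_id = ClassConfig.tf_class_id, ClassConfig.regulatory_class_id
    if tf_id in memberships and reg_id in memberships:
        memberships[REGULATORY_MINUS_TF_ID] = class_minus_class(
            memberships[reg_id], memberships[tf_id]
        )
    names = dict(DEFAULT_CLASS_NAMES)
    names[REGULATORY_MINUS_TF_ID] = "regulation of cellular processes (TFs excluded)"
    results = enrichment_scan(cohort, memberships, min_size=min_size, class_names=names)
    return enrichment_table(results)


def run_pipeline(
    config: PipelineConfig, records: Sequence[ProteinRecord] | None = None
) -> dict:
    """Run the full analysis; returns the report bundle as a dict.

    ``records`` may be passed directly (e.g. from the synthetic generator),
    otherwise they are loaded from the configured paths.  If
    ``config.outdir`` is set the bundle is also written to disk.
    """
    if records is None:
        records = load_records(config)

    all_cohort = build_cohort(records, "ALL")
    cohort = select_cohort(records, config)
    strata = stratify_by_tm(all_cohort.records, all_cohort.toxic_flags)

    featurizer = SequenceFeaturizer(pka_set=config.pka_set)
    features = featurizer.transform(cohort.records)
    flags = cohort.toxic_flags

    tests = _feature_tests(features, flags)
    profiles, fits = _bin_profiles(features, flags, config.bins, config.seed)
    enrich = _enrichment(cohort, config.min_class_size)
    reports = clf.ablation_compare(
        features,
        flags,
        seed=config.seed,
        n_repetitions=config.n_repetitions,
        n_estimators=config.n_estimators,
        holdout=config.holdout,
    )

    bundle = {
        "config": config.to_dict(),
        "seed": config.seed,
        "cohort_summary": {
            "all": cohort_summary(all_cohort),
            "analysis": cohort_summary(cohort),
        },
        "tm_strata": strata.to_dict(orient="records"),
        "feature_tests": tests.to_dict(orient="records"),
        "bin_fits": fits,
        "bin_profiles": profiles.to_dict(orient="records"),
        "enrichment": enrich.to_dict(orient="records"),
        "classification": [dataclasses.asdict(r) for r in reports],
    }
    if config.outdir:
        write_bundle(bundle, tests, profiles, enrich, Path(config.outdir))
    return bundle


def write_bundle(
    bundle: dict,
    tests: pd.DataFrame,
    profiles: pd.DataFrame,
    enrich: pd.DataFrame,
    outdir: Path,
) -> None:
    """Write the report bundle: JSON + per-table TSVs + plain-text summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    tests.to_csv(outdir / "feature_tests.tsv", sep="\t", index=False, float_format="%.6g")
    profiles.to_csv(outdir / "bin_profiles.tsv", sep="\t", index=False, float_format="%.6g")
    enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(render_summary(bundle))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def render_summary(bundle: dict) -> str:
    """Human-readable digest of a report bundle."""
    lines = []
    s_all = bundle["cohort_summary"]["all"]
    s_coh = bundle["cohort_summary"]["analysis"]
    lines.append(f"seed: {bundle['seed']}")
    lines.append(
        f"all clones: n={s_all['n']}, toxic={s_all['n_toxic']} "
        f"({s_all['percent_toxic']:.1f}%), growth-inhibited "
        f"{s_all['growth_inhibited_percent']:.1f}%"
    )
    lines.append(
        f"analysis cohort ({s_coh['cohort_name']}): n={s_coh['n']}, "
        f"toxic={s_coh['n_toxic']} ({s_coh['percent_toxic']:.1f}%)"
    )
    lines.append("TM strata (all clones):")
    for row in bundle["tm_strata"]:
        pct = row["percent_toxic"]
        pct_s = f"{pct:.1f}%" if pct == pct else "NA"
        lines.append(f"  TM {row['stratum']}: n={row['n']}, toxic {pct_s}")
    lines.append("feature tests (toxic vs non-toxic):")
    for row in bundle["feature_tests"]:
        lines.append(
            f"  {row['feature']}: {row['test']} p={row['p_value']:.3g}, "
            f"centers {row['toxic_center']:.4g} vs {row['nontoxic_center']:.4g}"
        )
    lines.append("enrichment (p ascending):")
    for row in bundle["enrichment"]:
        lines.append(
            f"  {row['class_name']}: {row['percent_toxic_in_class']:.1f}% toxic "
            f"(background {row['background_percent']:.1f}%), p={row['p_value']:.3g}"
        )
    lines.append("classification (mean ROC-AUC over repetitions):")
    for rep in bundle["classification"]:
        lines.append(
            f"  {rep['feature_subset_name']}: {rep['mean_auc']:.3f} "
            f"(n_rep={rep['n_repetitions']})"
        )
    return "\n".join(lines) + "\n"
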