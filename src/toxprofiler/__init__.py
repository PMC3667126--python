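"""toxprofiler: sequence and functional determinants of protein
overexpression toxicity in bacteria.

The package profiles an overexpression screen: it labels toxic clones,
computes cheap sequence features (charged-residue counts, isoelectric
point, length, Kyte-Doolittle hydropathy), runs the association battery
(rank-sum, Welch t, Fisher exact, equal-frequency bin trends, functional
class enrichment) and measures predictive power with a balanced-resampling
random-forest protocol.  A synthetic proteome generator with known ground
truth makes every stage testable offline.
"""

from .data_io import (
    FluorescenceClass,
    GrowthClass,
    LabeledCohort,
    Localization,
    ProteinRecord,
    build_cohort,
    build_records,
    cohort_summary,
    filter_cytoplasmic,
    filter_secretory,
    label_toxicity,
    parse_tmhmm,
    read_annotations,
    read_fasta,
    stratify_by_tm,
)
from .features import (
    ClassConfig,
    FeatureVector,
    PkaSet,
    PKA_SETS,
    SequenceFeaturizer,
    compute_pI,
    count_charged,
    featurize,
    featurize_all,
    mean_hydropathy,
    net_charge,
)
from .stats import (
    BinProfile,
    EnrichmentResult,
    TestResult,
    bin_toxicity_trend,
    class_minus_class,
    enrichment_scan,
    equal_freq_bins,
    fisher_2x2,
    rank_sum_test,
    two_sample_t,
)
from .classify import (
    BalancedForestProtocol,
    ClassificationReport,
    FEATURE_SUBSETS,
    ablation_compare,
    balanced_subsample,
    roc_auc,
    run_protocol,
)
from .synthetic import (
    GeneratorConfig,
    ToxicityCoefficients,
    generate_proteome,
    generate_sequence,
    memberships_from_records,
    write_outputs,
)
from .pipeline import PipelineConfig, run_pipeline

__version__ = "0.1.0"

__all__ = [
    "BalancedForestProtocol",
    "BinProfile",
    "ClassConfig",
    "ClassificationReport",
    "EnrichmentResult",
    "FEATURE_SUBSETS",
    "FeatureVector",
    "FluorescenceClass",
    "GeneratorConfig",
    "GrowthClass",
    "LabeledCohort",
    "Localization",
    "PKA_SETS",
    "PipelineConfig",
    "PkaSet",
    "ProteinRecord",
    "SequenceFeaturizer",
    "TestResult",
    "ToxicityCoefficients",
    "ablation_compare",
    "balanced_subsample",
    "bin_toxicity_trend",
    "build_cohort",
    "build_records",
    "class_minus_class",
    "cohort_summary",
    "compute_pI",
    "count_charged",
    "enrichment_scan",
    "equal_freq_bins",
    "featurize",
    "featurize_all",
    "filter_cytoplasmic",
    "filter_secretory",
    "fisher_2x2",
    "generate_proteome",
    "generate_sequence",
    "label_toxicity",
    "mean_hydropathy",
    "memberships_from_records",
    "net_charge",
    "parse_tmhmm",
    "rank_sum_test",
    "read_annotations",
    "read_fasta",
    "roc_auc",
    "run_pipeline",
    "run_protocol",
    "stratify_by_tm",
    "two_sample_t",
    "write_outputs",
]
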