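import numpy as np
import pytest

from toxprofiler import (
    FluorescenceClass,
    GeneratorConfig,
    GrowthClass,
    Localization,
    ProteinRecord,
    generate_proteome,
)


@pytest.fixture(scope="session")
def default_proteome():
    """One default synthetic proteome (seed 1), shared across test modules."""
    return generate_proteome(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_proteome():
    """A small synthetic proteome for fast feature round-trip checks."""
    return generate_proteome(GeneratorConfig(n_proteins=200, seed=7))


def _rec(pid, seq, growth, fluor, loc=(), tm=0, go=()):
    return ProteinRecord(
        id=pid,
        sequence=seq,
        growth_class=GrowthClass[growth],
        fluorescence_class=FluorescenceClass[fluor],
        localization=frozenset(Localization[t] for t in loc),
        tm_count=tm,
        go_classes=frozenset(go),
    )


@pytest.fixture()
def hand_records():
    """Ten hand-written records with known cohort tallies.

    6 cytoplasmic (3 toxic), 4 secretory/TM (3 toxic); TM strata:
    tm=0 n=8 (4 toxic), tm=1 n=1 (1 toxic), tm>=2 n=1 (1 toxic).
    """
    return [
        _rec("c1", "MKRDE", "ALMOST_NO_GROWTH", "NO_FLUORESCENCE"),
        _rec("c2", "MKKKK", "ALMOST_NO_GROWTH", "NO_FLUORESCENCE", go=("GO:0001071",)),
        _rec("c3", "MDDEE", "ALMOST_NO_GROWTH", "NO_FLUORESCENCE"),
        _rec("c4", "MAAAG", "SLOW_GROWTH", "FLUORESCENCE"),
        _rec("c5", "MGGGG", "NORMAL_GROWTH", "HIGH_FLUORESCENCE", go=("GO:0003824",)),
        _rec("c6", "MAVLI", "ALMOST_NO_GROWTH", "FLUORESCENCE"),
        _rec("s1", "MILVA", "ALMOST_NO_GROWTH", "NO_FLUORESCENCE", loc=("MEMBRANE",), tm=1),
        _rec("s2", "MILVF", "ALMOST_NO_GROWTH", "NO_FLUORESCENCE", loc=("MEMBRANE",), tm=3),
        _rec("s3", "MNQSA", "ALMOST_NO_GROWTH", "NO_FLUORESCENCE", loc=("PERIPLASMIC_SPACE",)),
        _rec("s4", "MNQST", "NORMAL_GROWTH", "FLUORESCENCE", loc=("OUTER_MEMBRANE",)),
    ]
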