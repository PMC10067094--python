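import pytest

from tp53kit import (
    Cohort,
    ReferenceBundle,
    SimulationConfig,
    annotate_cohort,
    read_clinical_table,
    read_variant_table,
    simulate_cohort,
    synthetic_ea_score_table,
)


@pytest.fixture(scope="session")
def refs():
    return ReferenceBundle.default(ea_scores=synthetic_ea_score_table())


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic cohort (n=210, seed 11), generated once."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_files(sim_default, tmp_path_factory):
    """The default cohort written to disk in the TSV dialects the readers use."""
    d = tmp_path_factory.mktemp("simcohort")
    sim_default.write(d)
    return d


@pytest.fixture(scope="session")
def annotated_cohort(sim_files, refs):
    clinical = read_clinical_table(sim_files / "clinical.tsv")
    variants = read_variant_table(sim_files / "variants.tsv")
    return annotate_cohort(Cohort(clinical, variants), refs)
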