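import hypothesis
import pytest

hypothesis.settings.register_profile(
    "det", derandomize=True, deadline=None, max_examples=60)
hypothesis.settings.load_profile("det")

from disorderdb import (OrganismInput, RunConfig, SyntheticProteomeSpec,
                        generate_synthetic_proteome, run_pipeline)
from disorderdb.synthetic import PlantedSegmentRule


@pytest.fixture(scope="session")
def synthetic_proteome():
    """A small deterministic proteome with planted disordered segments."""
    spec = SyntheticProteomeSpec(
        n_proteins=12, length_range=(60, 200), fraction_ineligible=0.25,
        planted_disorder=(PlantedSegmentRule(length=25),), seed=11)
    fasta, truth = generate_synthetic_proteome(spec)
    return spec, fasta, truth


@pytest.fixture(scope="session")
def pipeline_db(tmp_path_factory, synthetic_proteome):
    """A database written by a full builtin-mode pipeline run."""
    _, fasta, _ = synthetic_proteome
    root = tmp_path_factory.mktemp("pipeline")
    fasta_path = root / "synthetic.fasta"
    fasta_path.write_text(fasta)
    db_path = root / "synthetic.db"
    config = RunConfig(
        organisms=(OrganismInput(label="synthetica", fasta_path=str(fasta_path)),),
        output_path=str(db_path))
    path, report = run_pipeline(config)
    return path, report
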