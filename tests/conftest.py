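import pytest

import crossmir as cm


def make_db(*gene_sets, ids=None):
    """Small literal transaction database for hand-checked cases."""
    ids = ids or [f"P{i + 1}" for i in range(len(gene_sets))]
    return cm.TransactionDB(
        transactions=[(pid, frozenset(genes))
                      for pid, genes in zip(ids, gene_sets)])


@pytest.fixture(scope="session")
def default_bundle():
    """Synthetic inputs under the default (study-condition) config."""
    return cm.generate_bundle()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic config."""
    out = tmp_path_factory.mktemp("bundle")
    config = cm.PipelineConfig(synthetic=cm.SyntheticConfig(),
                               out_dir=str(out))
    return cm.run_pipeline(config)


@pytest.fixture()
def obs():
    def _obs(mirna, disease, direction, study="S1"):
        return cm.MirnaObservation(mirna_id=mirna, disease=disease,
                                   direction=cm.Direction(direction),
                                   study_id=study)
    return _obs
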