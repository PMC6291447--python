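import pytest

from sasdiag import diagnosis, fixtures


@pytest.fixture(scope="session")
def tables_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("tables")
    return fixtures.make_tables(out, seed=0)


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    return fixtures.make_full_demo(tmp_path_factory.mktemp("demo"), seed=0)


@pytest.fixture(scope="session")
def demo_config(demo):
    return diagnosis.PipelineConfig(
        ref_seq=demo.ref_seq,
        structures=demo.structures,
        variant_table=demo.variant_table,
        foldx=demo.foldx,
    )


@pytest.fixture(scope="session")
def demo_result(demo_config):
    return diagnosis.run_pipeline(demo_config)
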