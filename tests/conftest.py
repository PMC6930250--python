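import pandas as pd
import pytest

import mitosrna as m


@pytest.fixture(scope="session")
def toy_genome():
    return m.make_toy_genome(seed=1, length=2000)


@pytest.fixture(scope="session")
def truth(toy_genome):
    return m.plant_fragments(toy_genome, m.default_fragments(toy_genome), seed=1)


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """A scaled-down simulated study run end to end through the pipeline.

    Two developmental stages x five treatments x three replicates with a
    light background, plus the full output bundle.
    """
    root = tmp_path_factory.mktemp("study")
    cfg = m.PipelineConfig(
        output_dir=str(root / "results"), seed=7,
        sim={"stages": ("WS36", "WS40"), "replicates": 3,
             "background_reads": 100, "outdir": str(root / "sim")})
    m.simulate(cfg)
    summary = m.run(cfg)
    return cfg, summary


@pytest.fixture(scope="session")
def sim_truth(sim_study):
    cfg, _ = sim_study
    return pd.read_csv(cfg.samples.replace("samples.tsv", "truth.tsv"), sep="\t")
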