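import pytest

from dicoex import run_dce, run_deg
from dicoex import synthetic_data as sd
from dicoex.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def platform_pair():
    """The desk-scale two-platform design: large (93 WT / 415 MUT) and small
    (14 WT / 166 MUT) cohorts sharing half of 50 planted DE genes and 20
    planted co-expression blocks."""
    cfg = sd.default_config(seed=1)
    (ds_a, truth_a), (ds_b, truth_b) = sd.simulate_pair_of_platforms(cfg)
    return cfg, ds_a, truth_a, ds_b, truth_b


@pytest.fixture(scope="session")
def deg_pair(platform_pair):
    _, ds_a, _, ds_b, _ = platform_pair
    return run_deg(ds_a, method="bonferroni"), run_deg(ds_b, method="bh")


@pytest.fixture(scope="session")
def dce_pair(platform_pair):
    _, ds_a, _, ds_b, _ = platform_pair
    return run_dce(ds_a, method="bonferroni"), run_dce(ds_b, method="bh")


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the bundled synthetic design."""
    root = tmp_path_factory.mktemp("demo")
    cfg = sd.default_config(seed=1)
    paths = sd.write_demo_inputs(cfg, root)
    pcfg = PipelineConfig.from_yaml(paths["pipeline_config"])
    manifest = run_all(pcfg)
    (ds_a, truth_a), (ds_b, truth_b) = sd.simulate_pair_of_platforms(cfg)
    return {
        "cfg": cfg,
        "paths": paths,
        "pipeline_config": pcfg,
        "manifest": manifest,
        "out_dir": pcfg.out_dir,
        "truth_a": truth_a,
        "truth_b": truth_b,
    }
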