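import numpy as np
import pandas as pd
import pytest

from scfrag import GenomeModel, load_fragments, load_taxa, preset, simulate_cohort


@pytest.fixture(scope="session")
def genome():
    return GenomeModel.grch38()


@pytest.fixture(scope="session")
def noncancer_sample():
    """One jagged, short-enriched sample with sequences (20k fragments)."""
    from scfrag import simulate_sample

    cfg = preset("noncancer_like", n_fragments=20_000, seed=5)
    return simulate_sample(cfg, sample_id="NC1")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A written-to-disk 3+3 cohort at reduced depth, with its manifest."""
    out = tmp_path_factory.mktemp("cohort")
    cfg_a = preset("gc_like", n_fragments=4_000, seed=11)
    cfg_b = preset("noncancer_like", n_fragments=4_000, seed=11)
    manifest = simulate_cohort(cfg_a, cfg_b, 3, out, master_seed=11)
    return manifest


@pytest.fixture(scope="session")
def small_cohort_loaded(small_cohort):
    samples = {
        sid: load_fragments(path, sample_id=sid)
        for sid, path in small_cohort["fragment_files"].items()
    }
    groups = pd.Series(small_cohort["groups"])
    taxa = load_taxa(small_cohort["taxa_file"])
    return samples, groups, taxa


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240)
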