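import pandas as pd
import pytest

from polyase import SimConfig, build_testable_units, filter_variants, simulate_fixture


@pytest.fixture(scope="session")
def small_panel():
    """A small mixed-ploid panel with ASE truth, shared across tests."""
    cfg = SimConfig(n_transcripts=40, seed=11)
    calls, counts, truth = simulate_fixture(cfg)
    return cfg, calls, counts, truth


@pytest.fixture(scope="session")
def small_units(small_panel):
    _, calls, counts, _ = small_panel
    return build_testable_units(filter_variants(calls), counts)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The same small panel serialized to disk in all input formats."""
    cfg = SimConfig(n_transcripts=40, seed=11)
    out = tmp_path_factory.mktemp("fixture")
    simulate_fixture(cfg, out)
    return out


def make_units(rows):
    """Build a testable-unit table from (tx, pos, geno, alpha, beta, y_r, n_r) tuples."""
    recs = []
    for tx, pos, geno, alpha, beta, y_r, n_r in rows:
        recs.append(
            {
                "transcript": tx,
                "position": pos,
                "genotype": geno,
                "alpha": alpha,
                "beta": beta,
                "ploidy": alpha + beta,
                "gbs_depth": 30,
                "P": alpha / (alpha + beta),
                "y_r": tuple(y_r),
                "n_r": tuple(n_r),
                "pooled_y": sum(y_r),
                "pooled_n": sum(n_r),
            }
        )
    return pd.DataFrame(recs)
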