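import pytest

from volatrank import (
    AttractivenessRanking,
    SynthConfig,
    generate_profiles,
)


@pytest.fixture(scope="session")
def noiseless():
    """Default-geometry synthetic instance at zero noise: (cfg, matrix, truth)."""
    cfg = SynthConfig(noise_sd=0.0)
    matrix, truth = generate_profiles(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def noiseless_ranking(noiseless):
    """The planted ranking of the noiseless instance as a ranking object."""
    _, _, truth = noiseless
    return AttractivenessRanking.from_ranks(
        {p: i + 1 for i, p in enumerate(truth.true_ranking)}
    )


@pytest.fixture()
def wide_csv(tmp_path):
    path = tmp_path / "profiles.csv"
    path.write_text(
        "product_id,ethanol,ethyl acetate,sorbic acid\n"
        "P1,50,30,20\n"
        "P2,10,40,50\n"
    )
    return path


@pytest.fixture()
def long_csv(tmp_path):
    path = tmp_path / "profiles_long.csv"
    path.write_text(
        "product_id,compound,proportion\n"
        "P1,ethanol,50\n"
        "P1,ethyl acetate,30\n"
        "P1,sorbic acid,20\n"
        "P2,ethanol,60\n"
        "P2,sorbic acid,40\n"
    )
    return path
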