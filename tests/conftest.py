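import numpy as np
import pytest

import asircast as ac


def build_pipeline(spec: ac.SyntheticSpec, boundary_year: int = 2016):
    """panel -> scaler -> standardized panel -> features -> windows -> split."""
    panel = ac.generate_panel(spec)
    scaler = ac.fit_standardizer(panel, (int(panel.years[0]), boundary_year))
    std = ac.apply_standardizer(panel, scaler)
    fm = ac.build_feature_matrix(std)
    ds = ac.make_windows(fm, std)
    split = ac.split_sequential(ds, boundary_year)
    return {"panel": panel, "scaler": scaler, "std": std, "fm": fm,
            "ds": ds, "split": split}


@pytest.fixture(scope="session")
def default_spec():
    return ac.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def default_panel(default_spec):
    return ac.generate_panel(default_spec)


@pytest.fixture(scope="session")
def pipeline(default_spec):
    return build_pipeline(default_spec)


@pytest.fixture(scope="session")
def tiny_model():
    """Tiny deterministic model: d_h=2, T=3, D=6, G=2, no batch norm."""
    hp = ac.Hyperparameters(d_h=2, n_lstm_layers=2, heads_per_scale=2,
                            scales=((1, 1), (1, 2), (2, 3)), batchnorm=False,
                            dropout=0.0)
    return ac.DualPathwayModel(n_features=6, n_groups=2, window=3, hp=hp, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
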