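import numpy as np
import pytest

from circsync.datasets import StudyDataset, TimeSeriesExpression

ZT12 = np.arange(0.0, 24.0, 2.0)


def make_series(values, tissue="liver", condition="ALF", genes=None, timepoints=None):
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    if timepoints is None:
        timepoints = np.linspace(0.0, 22.0, values.shape[1])
    return TimeSeriesExpression(
        tissue_id=tissue,
        condition_id=condition,
        genes=tuple(genes),
        timepoints_h=np.asarray(timepoints, dtype=float),
        values=values,
        replicate_averaged=True,
    )


def cosine_profile(phase_h, amplitude=1.0, baseline=2.0, timepoints=ZT12):
    return baseline + amplitude * np.cos(2 * np.pi * (timepoints - phase_h) / 24.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_series(rng):
    """20 non-constant random gene profiles over the 12-point grid."""
    values = rng.gamma(2.0, 2.0, size=(20, 12)) + 0.1
    return make_series(values, timepoints=ZT12)


@pytest.fixture
def two_tissue_dataset(rng):
    """Small two-condition, three-tissue dataset of rhythmic genes."""
    genes = [f"g{i}" for i in range(8)]
    phases = rng.uniform(0, 24, size=8)
    series = {}
    for cond in ("ALF", "TRF"):
        for t_i, tissue in enumerate(("liver", "heart", "lung")):
            jitter = rng.normal(0, 1.0, size=8)
            vals = np.array(
                [cosine_profile(p + j, amplitude=2.0) for p, j in zip(phases, jitter)]
            )
            vals += rng.normal(0, 0.05, size=vals.shape)
            series[(cond, tissue)] = make_series(
                vals, tissue=tissue, condition=cond, genes=genes, timepoints=ZT12
            )
    return StudyDataset(
        conditions=("ALF", "TRF"),
        tissues=("liver", "heart", "lung"),
        series=series,
    )
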