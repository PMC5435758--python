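import numpy as np
import pytest

from gradedbold import HypercapniaLevel, graded_bold


def make_levels(m, kappa, cbf_ratios, doses, pairing="empirical"):
    """Noiseless levels generated by the forward model (shared oracle input)."""
    return [
        HypercapniaLevel(
            delta_petco2=dp,
            bold_frac=graded_bold(m, kappa, f, dp, pairing),
            cbf_ratio=f,
        )
        for f, dp in zip(cbf_ratios, doses)
    ]


@pytest.fixture
def gm_levels():
    """Two noiseless levels from gray-matter-like truth (M=8.6%, kappa=-1.3%/mmHg)."""
    return make_levels(0.086, -0.013, (1.13, 1.17), (4.8, 8.4))


@pytest.fixture
def level_factory():
    return make_levels


def interleaved_series(echo1, echo2, tr=1.0, te1=0.003, te2=0.030, first="tag"):
    """Small hand-built dual-echo series with alternating labels."""
    from gradedbold import DualEchoSeries

    n = len(echo1)
    other = "control" if first == "tag" else "tag"
    labels = np.where(np.arange(n) % 2 == 0, first, other)
    return DualEchoSeries(
        time=np.arange(n) * tr,
        label=labels,
        echo1=np.asarray(echo1, dtype=float),
        echo2=np.asarray(echo2, dtype=float),
        te1=te1,
        te2=te2,
        tr=tr,
    )


@pytest.fixture
def series_factory():
    return interleaved_series
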