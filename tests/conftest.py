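import numpy as np
import pytest

from clonaltide.profile import RegionCall, build_vaf_matrix
from clonaltide.simulate import SimConfig, simulate_tumour


def calls_from_truth(truth, noise_free=False, normal_depth=500):
    """Turn simulator output into per-region RegionCall lists.

    With ``noise_free`` the alt counts are replaced by round(depth * true VAF),
    the infinite-depth surrogate used for limiting-property checks.
    """
    out = {}
    for r in truth.true_vaf.columns:
        calls = []
        for m in truth.true_vaf.index:
            depth = int(truth.depth.loc[m, r])
            alt = (
                int(round(depth * truth.true_vaf.loc[m, r]))
                if noise_free
                else int(truth.alt.loc[m, r])
            )
            calls.append(
                RegionCall(
                    mutation=truth.records[m],
                    region=r,
                    depth=depth,
                    alt_reads=alt,
                    normal_depth=normal_depth,
                    normal_alt=0,
                )
            )
        out[r] = calls
    return out


def matrix_from_truth(truth, noise_free=False):
    return build_vaf_matrix(calls_from_truth(truth, noise_free=noise_free), truth.tumour_id)


class CountsView:
    """Minimal VafMatrix-shaped view straight onto simulator truth counts."""

    def __init__(self, truth):
        self.depth = truth.depth
        self.alt = truth.alt
        self.vaf = truth.alt / truth.depth


@pytest.fixture
def small_truth():
    return simulate_tumour(SimConfig(n_clones=3, n_mutations=12, mean_depth=500, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
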