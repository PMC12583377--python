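"""Shared fixtures: small synthetic systems used across module tests."""

import numpy as np
import pytest

from roimcr.assembly import AugmentedMatrix
from roimcr.synthetic import (
    GroundTruthComponent,
    NoiseModel,
    SampleInfo,
    generate_design,
)


@pytest.fixture(scope="session")
def design():
    return generate_design()


@pytest.fixture(scope="session")
def design_qc():
    return generate_design(include_qc=True)


def make_bilinear_system(n_blocks=5, n_components=3, n_scans=80, n_cols=12, seed=3, amp_range=(1e4, 1e5)):
    """Exactly bilinear multi-block data with known C and S factors.

    Spectra occupy disjoint column groups (full selectivity), profiles
    are Gaussians with slightly jittered apexes per block.
    """
    rng = np.random.default_rng(seed)
    rts = np.arange(n_scans) * 0.4
    S = np.zeros((n_cols, n_components))
    per = n_cols // n_components
    pattern = [1.0, 0.4, 0.15, 0.05]
    for k in range(n_components):
        for j in range(per):
            S[per * k + j, k] = pattern[j % len(pattern)]
    blocks, C_blocks = [], []
    block_index, rt_axes = {}, {}
    row0 = 0
    for b in range(n_blocks):
        C = np.zeros((n_scans, n_components))
        for k in range(n_components):
            amp = rng.uniform(*amp_range)
            center = 8 + 8 * k + rng.normal(0, 0.5)
            C[:, k] = amp * np.exp(-0.5 * ((rts - center) / 2.5) ** 2)
        blocks.append(C @ S.T)
        C_blocks.append(C)
        block_index[f"s{b}"] = slice(row0, row0 + n_scans)
        rt_axes[f"s{b}"] = rts
        row0 += n_scans
    D = np.vstack(blocks)
    aug = AugmentedMatrix(D, block_index, np.linspace(100, 101, n_cols), rt_axes, (0.0, float(rts[-1])))
    return aug, np.vstack(C_blocks), S


@pytest.fixture
def bilinear():
    return make_bilinear_system()


@pytest.fixture
def study_sample():
    return SampleInfo("C1_S1", "control", "S1", 1, "study")


@pytest.fixture
def quiet_noise():
    return NoiseModel.quiet()


def simple_component(**kw):
    defaults = dict(
        component_id="cpX",
        mz=300.1234,
        satellites=[(1.00336, 0.3)],
        rt_center=600.0,
        sigma=6.0,
        base_area=1e6,
    )
    defaults.update(kw)
    return GroundTruthComponent(**defaults)
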