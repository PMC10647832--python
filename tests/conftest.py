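import numpy as np
import pytest

from radiorisk.io import MpmriStudy, RoiMask, VolumeGrid
from radiorisk.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_study(seed: int = 0, shape=(32, 32, 20), spacing=(1.0, 1.0, 3.0)) -> MpmriStudy:
    """A small hand-built study with all masks, for unit tests."""
    r = np.random.default_rng(seed)
    volumes = {}
    base = {"t2": 200.0, "adc": 1200.0, "b": 50.0}
    for seq, mean in base.items():
        vals = r.normal(mean, 0.05 * mean, shape)
        volumes[seq] = VolumeGrid(np.clip(vals, 1, None), spacing, seq)

    def block(sl):
        m = np.zeros(shape, bool)
        m[sl] = True
        return m

    masks = [
        RoiMask(block(np.s_[12:18, 12:18, 8:12]), "L", "1"),
        RoiMask(block(np.s_[5:10, 20:25, 8:12]), "NAPZ"),
        RoiMask(block(np.s_[20:25, 20:25, 8:12]), "NATZ"),
        RoiMask(block(np.s_[1:5, 1:5, 6:14]), "GM"),
        RoiMask(block(np.s_[26:31, 1:5, 6:14]), "femoral_head"),
        RoiMask(block(np.s_[12:20, 26:31, 6:14]), "bladder"),
    ]
    # distinct reference-tissue means on t2 (GM < femoral head < bladder)
    t2 = volumes["t2"].values
    t2[masks[3].mask] = r.normal(100, 4, masks[3].mask.sum())
    t2[masks[4].mask] = r.normal(300, 10, masks[4].mask.sum())
    t2[masks[5].mask] = r.normal(900, 25, masks[5].mask.sum())
    b = volumes["b"].values
    b[masks[3].mask] = r.normal(120, 5, masks[3].mask.sum())
    return MpmriStudy("P1", "P1_E1", volumes, masks)


@pytest.fixture()
def study():
    return make_study()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort (single lesions)."""
    cfg = CohortConfig(n_patients=14, lesion_count_probs={1: 0.7, 2: 0.3}, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def analysis_table(small_cohort):
    from radiorisk.pipeline import build_analysis_table

    return build_analysis_table(small_cohort)
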