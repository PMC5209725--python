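import numpy as np
import pytest

from hcpanel import (
    ClinicalGeneSet,
    DepthProfile,
    GenomicInterval,
    Panel,
    Roi,
    SimulationConfig,
    simulate_panel,
)


@pytest.fixture
def tiny_panel() -> Panel:
    """Two genes, three hand-placed ROIs on one chromosome (no padding)."""
    return Panel(
        name="tiny",
        rois=[
            Roi("BRCA1", 1, GenomicInterval("chr17", 100, 200), "+"),
            Roi("BRCA1", 2, GenomicInterval("chr17", 500, 560), "+"),
            Roi("MLH1", 1, GenomicInterval("chr3", 1000, 1100), "-"),
        ],
    )


@pytest.fixture
def tiny_geneset() -> ClinicalGeneSet:
    return ClinicalGeneSet(name="HBOC", genes=frozenset({"BRCA1"}))


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture
def sim_panel(sim_config) -> Panel:
    return simulate_panel(sim_config)


def constant_profile(panel: Panel, depth: int, sample: str = "S1") -> DepthProfile:
    return DepthProfile.constant(panel, sample, depth)


def random_profile(panel: Panel, rng: np.random.Generator, sample: str = "S1") -> DepthProfile:
    arrays = [rng.integers(0, 120, size=len(r)).astype(np.int64) for r in panel.rois]
    return DepthProfile(sample, panel, arrays)
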