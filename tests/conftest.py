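"""Shared fixtures: panels and simulated families reused across the suite."""

from __future__ import annotations

import pytest

from alphapgt import FamilyConfig, build_default_panel, simulate_family
from alphapgt.sim import NOISELESS


@pytest.fixture(scope="session")
def default_config() -> FamilyConfig:
    return FamilyConfig("fam1", "father", "mother")


@pytest.fixture(scope="session")
def small_panel():
    """Fast panel: 100 backbone SNPs per autosome plus the 407 target SNPs."""
    return build_default_panel(n_backbone_per_chrom=100)


@pytest.fixture(scope="session")
def default_panel():
    """Desk-scale default panel (2,000 backbone SNPs per autosome)."""
    return build_default_panel()


@pytest.fixture(scope="session")
def clean_family(default_panel):
    """A noiseless 8-embryo euploid family."""
    return simulate_family(n_embryos=8, noise=NOISELESS, seed=11, panel=default_panel)


@pytest.fixture(scope="session")
def noisy_family(default_panel):
    """An 8-embryo euploid family under the default WGA noise model."""
    return simulate_family(n_embryos=8, seed=12, panel=default_panel)
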