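"""Shared fixtures: a small yeast-like chromosome model and probe panels."""

import numpy as np
import pytest

from repliq.copynumber import ProbeSpec
from repliq.simulate import Origin, ReplicationModel


@pytest.fixture
def rng():
    return np.random.default_rng(20180709)


@pytest.fixture
def chromosome_model():
    """400 kb chromosome, early origin at 50 kb, mid origin at 350 kb.

    Fork speed 5 kb/min puts the latest-replicating locus near 200 kb
    (trep = 35 min), giving a full early-to-late trep span of 5-35 min.
    """
    return ReplicationModel(
        chrom_length=400_000,
        origins=(Origin(50_000, 5.0), Origin(350_000, 12.0)),
        fork_speed_kb_min=5.0,
        chrom="chrT",
    )


@pytest.fixture
def control_probes():
    return [
        ProbeSpec("early_ctrl", "chrT", 49_900, 50_100, role="early_control"),
        ProbeSpec("late_ctrl", "chrT", 199_900, 200_100, role="late_control"),
    ]


@pytest.fixture
def panel_probes(control_probes):
    """Controls plus targets spanning early, mid and late trep."""
    return control_probes + [
        ProbeSpec("mid_early", "chrT", 99_900, 100_100),
        ProbeSpec("mid", "chrT", 124_900, 125_100),
        ProbeSpec("mid_late", "chrT", 164_900, 165_100),
    ]
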