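"""Shared fixtures: parameter sets, body geometries, synthetic rasters."""

import numpy as np
import pytest

from tegotae import BodyConfig, ControllerParams
from tegotae.gait import GaitDiagram
from tegotae.legs import LEGS, Leg


@pytest.fixture
def params():
    """Standard controller parameters (slow walk, neighbor feedback on)."""
    return ControllerParams(omega=2.0, sigma1=0.2, sigma2=1.2,
                            k_a=0.7, k_p=0.1, k_c=0.2,
                            A=15.0, B=20.0, B_prime=5.0)


@pytest.fixture
def body():
    return BodyConfig()


@pytest.fixture
def centroid_body():
    """Body whose two support triangles (L1,R2,L3) and (L2,R1,R3) both have
    their centroid at the body center, so a symmetric tripod stance shares
    the weight exactly equally."""
    attachments = {
        Leg.L1: (0.15, 0.10), Leg.L2: (0.0, 0.20), Leg.L3: (-0.15, 0.10),
        Leg.R1: (0.15, -0.10), Leg.R2: (0.0, -0.20), Leg.R3: (-0.15, -0.10),
    }
    return BodyConfig(leg_attachment=attachments)


def synth_diagram(offsets, duty, period=2.0, n_cycles=8, sample_dt=0.01,
                  legs=LEGS):
    """Synthesize a stance raster from per-leg touchdown offsets.

    ``offsets`` maps Leg -> touchdown time as a fraction of the period; legs
    not listed never touch ground.  Stance lasts ``duty`` of each cycle.
    """
    n = int(round(n_cycles * period / sample_dt)) + 1
    t = sample_dt * np.arange(n)
    raster = np.zeros((n, 6), dtype=np.uint8)
    for leg in legs:
        if leg not in offsets:
            continue
        phase = ((t / period) - offsets[leg]) % 1.0
        raster[:, leg.index] = (phase < duty).astype(np.uint8)
    return GaitDiagram(raster, sample_dt, threshold=1.0)
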