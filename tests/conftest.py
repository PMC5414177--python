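"""Shared fixtures: calibrated wild-type models and reusable scan results.

Calibrations and population scans are the expensive pieces, so they are
session-scoped and shared across test modules.
"""

import math

import pytest

from samsizer.calibration import calibrate_one_transition, calibrate_two_transition
from samsizer.experiments import two_transition_fold_scan
from samsizer.model_core import ModelParams, SizeDependence

G_WT = math.log(2.0) / 24.0     # wild-type RGR: 24 h doubling time


@pytest.fixture(scope="session")
def wt_sizer_params():
    """One-transition activator-accumulation sizer, calibrated, dt = 1 h."""
    return calibrate_one_transition(100.0, G_WT)


@pytest.fixture(scope="session")
def wt_sizer_fine():
    """Same sizer calibrated on a 0.1 h grid (continuous-limit checks)."""
    template = ModelParams(dt=0.1,
                           size_dependence=SizeDependence.PCDK_PROP_SIZE)
    return calibrate_one_transition(100.0, G_WT, template=template)


def _two_transition(sizer_at_g1s, sizer_at_g2m):
    template = ModelParams(two_transition=True, dt=0.1,
                           size_dependence=SizeDependence.PCDK_PROP_SIZE,
                           sizer_at_g1s=sizer_at_g1s,
                           sizer_at_g2m=sizer_at_g2m,
                           g_sd=0.2 * G_WT, d_sd=5.0)
    return calibrate_two_transition(100.0, 200.0, G_WT, template=template)


@pytest.fixture(scope="session")
def wt_two_transition_both():
    return _two_transition(True, True)


@pytest.fixture(scope="session")
def wt_two_transition_g1s_only():
    return _two_transition(True, False)


@pytest.fixture(scope="session")
def wt_two_transition_g2m_only():
    return _two_transition(False, True)


@pytest.fixture(scope="session")
def scan_g1s_only(wt_two_transition_g1s_only):
    """pCDK_M fold scan with size sensing only at G1/S."""
    return two_transition_fold_scan(wt_two_transition_g1s_only, "pCDK_M",
                                    seed=101)


@pytest.fixture(scope="session")
def scan_g2m_only(wt_two_transition_g2m_only):
    """pCDK_S fold scan with size sensing only at G2/M."""
    return two_transition_fold_scan(wt_two_transition_g2m_only, "pCDK_S",
                                    seed=102)


@pytest.fixture(scope="session")
def scan_both_m(wt_two_transition_both):
    """pCDK_M fold scan with size sensing at both transitions."""
    return two_transition_fold_scan(wt_two_transition_both, "pCDK_M",
                                    folds=(1.0, 1.5, 2.0, 2.5, 3.0),
                                    seed=103, duration=500.0, burn_in=150.0)
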