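"""Shared fixtures.

The expensive simulations run once per session: the default-protocol
programmed stimulation of the packaged isthmus fixture (the reentry
induction study) and the conduction-velocity cable.
"""

import numpy as np
import pytest

import infarctvt as iv
from infarctvt import monodomain as md


def make_cable(h_mm=0.1, length_mm=20.0, sigma_l=0.28, dt=0.02,
               n_beats=1, cycle_ms=600.0, duration_tail_ms=300.0):
    """End-paced 1D cable of normal myocardium; returns (grid, record)."""
    n = int(round(length_mm / h_mm))
    ct = np.full((n, 1, 1), md.CT_NORMAL, dtype=np.uint8)
    cp = md.ConductivityParams(sigma_longitudinal=sigma_l)
    grid = md.build_tissue_grid(ct, 0.0, (h_mm, h_mm, h_mm), cparams=cp)
    c = h_mm / 2.0
    stims = [md.StimulusEvent(5.0 + b * cycle_ms, 2.0, 60.0, (0.5, c, c), 1.0)
             for b in range(n_beats)]
    rec = md.run_monodomain(
        grid, stims, cycle_ms * (n_beats - 1) + duration_tail_ms, dt=dt,
        probes_mm=[(5.0, c, c), (15.0, c, c)])
    return grid, rec


@pytest.fixture(scope="session")
def cv_cable():
    """Six-beat 600 ms drive on a 2 cm cable at 0.1 mm spacing."""
    grid, rec = make_cable(n_beats=6)
    c = grid.spacing_mm[1] / 2.0
    cv = md.measure_cv(rec, (5.0, c, c), (15.0, c, c), beat="last")
    return grid, rec, cv


@pytest.fixture(scope="session")
def vt_outcome():
    """Default-protocol PES on the packaged isthmus fixture (the single
    expensive induction study of the suite)."""
    grid = iv.isthmus_fixture_grid()
    site = iv.ISTHMUS_FIXTURE["pes_site_mm"]
    outcome = iv.run_pes(grid, iv.PacingProtocol(), site)
    return grid, outcome


@pytest.fixture(scope="session")
def vt_location(vt_outcome):
    _, outcome = vt_outcome
    if not outcome.induced:
        pytest.fail("isthmus fixture failed to induce under the default "
                    "protocol; localization untestable")
    return iv.locate_reentry(outcome.record)


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Deterministic phantom whose segmentation must be exact."""
    spec = iv.PhantomSpec(matrix_size=(48, 48, 48), scar_radius=4.0,
                          gz_rim_width=1.5, infarct_center=(9.4, 9.4, 9.4),
                          noise_sd=0.0, normal_intensity_sd=0.0)
    img, lab = iv.generate_phantom(spec)
    return spec, img, lab


@pytest.fixture(scope="session")
def study_smoke():
    """One light resolution study reused by the smoke assertions."""
    proto = iv.PacingProtocol(n_s1=1, max_extrastimuli=1, min_coupling=520.0,
                              vt_duration=1500.0)
    spec = iv.study_phantom_spec()
    return iv.resolution_study(spec, [iv.MED_RES, iv.LOW_RES], proto)
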