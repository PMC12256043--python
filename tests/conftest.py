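"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from tpskit.kinetics import michaelis_menten


def mm_grid_search_oracle(
    S: np.ndarray,
    v: np.ndarray,
    km_center: float,
    vmax_center: float,
    n: int = 400,
    span: float = 5.0,
) -> tuple[float, float, float]:
    """Brute-force Michaelis–Menten least squares on an n×n log grid.

    Returns ``(vmax, km, log_step)`` where ``log_step`` is the natural-log
    grid resolution, the agreement tolerance for any optimizer under test.
    Deliberately independent of the package's fitting path.
    """
    kms = np.exp(np.linspace(np.log(km_center / span), np.log(km_center * span), n))
    vmaxs = np.exp(np.linspace(np.log(vmax_center / span), np.log(vmax_center * span), n))
    # SSE over the full grid via broadcasting: (n_km, n_vmax, n_points)
    pred = vmaxs[None, :, None] * S[None, None, :] / (kms[:, None, None] + S[None, None, :])
    sse = ((pred - v[None, None, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    log_step = float(np.log(kms[1]) - np.log(kms[0]))
    return float(vmaxs[j]), float(kms[i]), log_step


def assert_fit_matches_grid(fit, S, v, vmax_g, km_g, log_step):
    """Oracle agreement: the optimizer must be at least as good as the best
    grid point and sit within two grid steps of it in log space (the
    continuous optimum can legitimately fall up to a step away from the
    nearest grid node along a curved SSE valley)."""
    sse_fit = float(((michaelis_menten(S, fit.vmax_uM_per_s, fit.km_uM) - v) ** 2).sum())
    sse_grid = float(((michaelis_menten(S, vmax_g, km_g) - v) ** 2).sum())
    assert sse_fit <= sse_grid * (1 + 1e-9)
    assert abs(np.log(fit.km_uM) - np.log(km_g)) <= 2 * log_step
    assert abs(np.log(fit.vmax_uM_per_s) - np.log(vmax_g)) <= 2 * log_step


@pytest.fixture(scope="session")
def grid_oracle():
    return mm_grid_search_oracle
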