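from __future__ import annotations

import numpy as np
import pytest

from migrastat import SyntheticSpec, Trajectory2D, gen_ballistic


@pytest.fixture
def ballistic_traj() -> Trajectory2D:
    """Straight line at 0.008 mm/frame along +x, 1000 points."""
    return gen_ballistic(SyntheticSpec(kind="ballistic", n=1000, seed=0))


@pytest.fixture
def square_loop() -> Trajectory2D:
    """Closed unit-square path returning to the start."""
    pts = np.array(
        [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float
    )
    return Trajectory2D(cell_id="loop", positions=pts, dt=2.0)


def fbm2d(n: int, H: float, seed: int, step_scale: float = 0.008) -> Trajectory2D:
    """2D fractional Brownian trajectory built from two independent fGn axes."""
    from migrastat import gen_fgn

    x = np.cumsum(gen_fgn(SyntheticSpec(kind="fgn", H=H, n=n, seed=seed)).values)
    y = np.cumsum(gen_fgn(SyntheticSpec(kind="fgn", H=H, n=n, seed=seed + 500_000)).values)
    positions = np.vstack([[0.0, 0.0], np.column_stack([x, y]) * step_scale])
    return Trajectory2D(cell_id=f"fbm-H{H}-s{seed}", positions=positions, dt=2.0)
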