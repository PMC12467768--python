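"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from tangramcae import (
    CANONICAL_SHAPES,
    Piece,
    PieceType,
    SimFigureSpec,
    TangramFigure,
    gen_figures,
    make_schedule,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return Piece(PieceType.SQUARE, [(0, 0), (2, 0), (2, 2), (0, 2)])


@pytest.fixture
def small_triangle():
    return Piece(PieceType.SMALL_A, [(0, 0), (2, 0), (0, 2)])


@pytest.fixture(scope="session")
def scattered_figure():
    """Seven canonical pieces far apart: all-zero encoding."""
    pieces = []
    for k, (pid, verts) in enumerate(CANONICAL_SHAPES.items()):
        pieces.append(Piece(pid, np.asarray(verts) + np.array([20.0 * k, 0.0])))
    return TangramFigure(figure_id="scattered", pieces=pieces)


@pytest.fixture(scope="session")
def random_figures():
    """Twenty generated figures with ground-truth encodings."""
    return gen_figures(SimFigureSpec(seed=7), 20)


@pytest.fixture(scope="session")
def stim_table():
    """A small stimulus table with known dimension values."""
    rng = np.random.default_rng(99)
    n = 12
    return pd.DataFrame(
        {
            "figure_id": [f"f{i:02d}" for i in range(n)],
            "animacy_binary": np.tile([0, 1], n // 2),
            "abstraction": rng.uniform(0, 1, n),
            "lfd": rng.uniform(0, 1, n),
            "local_deviation": rng.uniform(0, 0.5, n),
            "group_index": np.arange(n) % 9 + 1,
            "is_tangram": True,
        }
    )


@pytest.fixture(scope="session")
def schedule(stim_table):
    return make_schedule(stim_table.figure_id.tolist(), n_subjects=1, seed=5)
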