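import numpy as np
import pytest

from actiwin import FeatureMatrix
from actiwin.synthetic import default_schedule, generate


@pytest.fixture(scope="session")
def short_recording():
    """10 s of each of the 12 activities at 100 Hz, three sensors, seeded."""
    return generate(default_schedule(10.0), seed=42)


@pytest.fixture(scope="session")
def toy_selection_matrix():
    """3 informative features, 3 exact duplicates, 6 pure-noise features (n=500)."""
    rng = np.random.default_rng(7)
    n = 500
    y = rng.integers(0, 3, n)
    f = [(y == c) + 0.1 * rng.standard_normal(n) for c in range(3)]
    cols = f + [c.copy() for c in f] + [rng.standard_normal(n) for _ in range(6)]
    return FeatureMatrix([f"f{i}" for i in range(12)], np.column_stack(cols), y)


def make_pamap2_rows(n_rows=10, activity=1, nan_cells=()):
    """Text rows in the 54-column protocol dialect, with recognizable accel values.

    Column c of row r holds r + c / 100 so a parsed value identifies its cell;
    ``nan_cells`` is an iterable of (row, column) to blank out.
    """
    lines = []
    for r in range(n_rows):
        vals = [f"{r * 0.01:.2f}", str(activity)] + [
            f"{r + c / 100:.2f}" for c in range(2, 54)
        ]
        for rr, cc in nan_cells:
            if rr == r:
                vals[cc] = "NaN"
        lines.append(" ".join(vals))
    return "\n".join(lines) + "\n"
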