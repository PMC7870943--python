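import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def halves_map():
    from printarray import make_printing_map

    return make_printing_map(7, 8, "segregated-halves")


@pytest.fixture
def mixed_map():
    from printarray import make_printing_map

    return make_printing_map(7, 8, "mixed")


def brute_force_si(labels: np.ndarray, h: int, include_self: bool = True):
    """Direct double-loop oracle for the local/global segregation index."""
    ny, nx = labels.shape
    s = np.full((ny, nx), np.nan)
    for r in range(ny):
        for c in range(nx):
            g = labels[r, c]
            if g == 0:
                continue
            win = labels[max(r - h, 0):r + h + 1, max(c - h, 0):c + h + 1]
            kin = int((win == g).sum())
            total = int((win > 0).sum())
            if not include_self:
                kin -= 1
                total -= 1
            s[r, c] = kin / total if total > 0 else np.nan
    vals = s[~np.isnan(s)]
    return s, (float(vals.mean()) if vals.size else np.nan, int(vals.size))
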