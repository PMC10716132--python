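import pandas as pd
import pytest

from zevequity.designation import designate
from zevequity.region import RegionSpec, generate_region


@pytest.fixture(scope="session")
def small_spec() -> RegionSpec:
    return RegionSpec(n_tracts=64, grid_extent_m=8000.0, n_trips=2000,
                      met_days=1, seed=11)


@pytest.fixture(scope="session")
def small_region(small_spec):
    return generate_region(small_spec)


@pytest.fixture(scope="session")
def designated_tracts(small_region) -> pd.DataFrame:
    return designate(small_region.tracts)


@pytest.fixture()
def toy_tracts() -> pd.DataFrame:
    """Four equal-population tracts on a 2x2 grid with distinct scores."""
    cell = 1000.0
    rows = []
    for i, (burden, pchar) in enumerate([(1.0, 1.0), (2.0, 2.0),
                                         (3.0, 3.0), (4.0, 4.0)]):
        r, c = divmod(i, 2)
        rows.append(dict(
            tract_id=f"T{i:04d}", row=r, col=c,
            x0=c * cell, y0=r * cell, x1=(c + 1) * cell, y1=(r + 1) * cell,
            cx=(c + 0.5) * cell, cy=(r + 0.5) * cell,
            population=1000, households=400,
            pollution_burden=burden, pop_characteristics=pchar,
            frac_Hispanic=0.5, frac_White=0.3, frac_AAPI=0.1,
            frac_AfricanAm=0.06, frac_OtherMult=0.03, frac_NativeAm=0.01))
    return pd.DataFrame(rows)
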