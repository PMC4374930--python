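import numpy as np
import pytest

from n2oiso import Dataset, IsotopeRecord


@pytest.fixture
def toy_csv(tmp_path):
    """Three well-formed rows, one per flux-relevant category."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "category,d15N,d18O,site,reference\n"
        "soil,-14.9,31.2,field A,ref1\n"
        "marine,6.6,47.4,station B,ref2\n"
        "troposphere,6.55,44.40,tower C,ref3\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(category="soil", **kwargs):
    kwargs.setdefault("d15N_bulk", -10.0)
    kwargs.setdefault("d18O", 30.0)
    return IsotopeRecord(category=category, **kwargs)


@pytest.fixture
def threshold_dataset():
    """Records straddling every filter threshold, with expected outcomes."""
    cases = [
        (make_record("soil", concentration_ppb=651.0), True),
        (make_record("soil", concentration_ppb=650.0), False),
        (make_record("soil"), False),  # no concentration: insufficient metadata
        (make_record("soil", is_emitted=True), True),  # criterion (i)
        (make_record("freshwater", saturation_pct=201.0), True),
        (make_record("freshwater", saturation_pct=200.0), False),
        (make_record("marine", saturation_pct=250.0, depth_m=50.0), True),
        (make_record("marine", saturation_pct=250.0, depth_m=150.0), False),
        (make_record("marine", saturation_pct=250.0), True),  # surface, depth absent
        (make_record("marine", saturation_pct=150.0, depth_m=50.0), False),
        (make_record("troposphere"), False),
        (make_record("groundwater", saturation_pct=500.0), False),
    ]
    return Dataset(records=[r for r, _ in cases]), [kept for _, kept in cases]
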