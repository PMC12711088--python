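import numpy as np
import pytest

from weanest.io import IndividualSeries


@pytest.fixture
def toy_csv(tmp_path):
    """6-row CSV, two individuals with 3 increments each (shuffled ages)."""
    p = tmp_path / "toy.csv"
    p.write_text(
        "sample_id,age_at_increment,d15N,d13C,tooth_type\n"
        "B,1.5,11.0,-19.0,dM2\n"
        "A,0.5,12.0,-18.5,M1\n"
        "A,2.5,10.0,-19.5,M1\n"
        "B,0.5,12.5,-18.0,dM2\n"
        "A,1.5,11.0,-19.0,M1\n"
        "B,2.5,10.5,-19.2,dM2\n"
    )
    return p


@pytest.fixture
def make_series():
    def _make(sample_id="S1", tooth="M1", ages=None, d15n=None, d13c=None):
        ages = np.asarray(ages if ages is not None else [0.5, 1.5, 2.5, 3.5])
        d15n = np.asarray(d15n if d15n is not None else [12.0, 11.0, 10.0, 10.0])
        d13c = np.asarray(d13c if d13c is not None else [-18.5, -19.0, -19.5, -19.5])
        return IndividualSeries(sample_id=sample_id, tooth_type=tooth,
                                ages=ages, d15n=d15n, d13c=d13c)

    return _make
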