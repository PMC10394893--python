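import numpy as np
import pytest

from nanotherm import nanoptics as no
from nanotherm.phantom import Label, Phantom
from nanotherm.pipeline import TreatmentPlan, run_treatment


@pytest.fixture(scope="session")
def gold():
    return no.load_gold_dielectric()


@pytest.fixture(scope="session")
def reference_rod():
    return no.NanorodSpec.from_aspect_ratio(54.2, 3.1)


def homogeneous_phantom(n=16, spacing_mm=1.0, label=Label.TISSUE):
    """All-body rectangular block, used by solver verification tests."""
    labels = np.full((n, n, n), label, dtype=np.int8)
    return Phantom(
        labels=labels,
        spacing_mm=spacing_mm,
        origin_mm=np.zeros(3),
        f_v=np.zeros((n, n, n)),
    )


@pytest.fixture(scope="session")
def scenario_runs():
    """The three treatment arms at the default study conditions (shared:
    these runs are the expensive part of the suite)."""
    out = {}
    for sc in ("laser_only", "IP", "IT"):
        report, fields = run_treatment(TreatmentPlan(scenario=sc, seed=1))
        out[sc] = (report, fields)
    return out
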