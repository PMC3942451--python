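import numpy as np
import pandas as pd
import pytest

import fgakit as fk
from fgakit.simulate import SimConfig, simulate_sequences


@pytest.fixture(scope="session")
def worked_distance_case():
    """The 4-sample two-group case with within distances 1 and between 3."""
    d = np.array(
        [[0, 1, 3, 3], [1, 0, 3, 3], [3, 3, 0, 1], [3, 3, 1, 0]], dtype=float
    )
    return d, ["A", "A", "B", "B"]


@pytest.fixture(scope="session")
def small_db():
    """Two simulated families (5 members, 98% identity) plus 30 decoys."""
    cfg = SimConfig(
        seed=11, n_families=2, members_per_family=5, member_identity=98.0,
        cds_length=240, n_background=30,
    )
    sim = simulate_sequences(cfg)
    return fk.build_motherdb(sim.targets, sim.background, k=12), sim


@pytest.fixture(scope="session")
def scan_fixture():
    """Hand-built 5-probe × 4-sample scan table with known QC outcomes."""
    probes = ["p1", "p2", "p3", "p4", "CORS_1"]
    samples = ["s1", "s2", "s3", "s4"]
    intensity = pd.DataFrame(
        [
            [5000.0, 5000, 5000, 5000],   # p1 clean
            [5000.0, 5000, 5000, 5000],   # p2: cv fails in s1
            [5000.0, 5000, 5000, 5000],   # p3: snr fails in s2
            [999.0, 1000, 5000, 5000],    # p4: intensity fails in s1 only
            [1000.0, 2000, 1500, 1500],   # CORS (exempt from intensity filter)
        ],
        index=probes, columns=samples,
    )
    cv = pd.DataFrame(0.1, index=probes, columns=samples)
    cv.loc["p2", "s1"] = 0.9
    snr = pd.DataFrame(10.0, index=probes, columns=samples)
    snr.loc["p3", "s2"] = 1.5
    roles = pd.Series(
        {"p1": "experimental", "p2": "experimental", "p3": "experimental",
         "p4": "experimental", "CORS_1": "cors"}
    )
    groups = pd.Series({"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"})
    return fk.ScanTable(intensity=intensity, roles=roles, groups=groups, cv=cv, snr=snr)


@pytest.fixture(scope="session")
def designed_probeset(small_db):
    """Probes designed on the simulated two-family database."""
    db, _ = small_db
    pset = fk.design_probes(db, per_target=2)
    assert pset.probes
    return pset
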