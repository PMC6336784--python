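import pandas as pd
import pytest

import polysel as ps


@pytest.fixture(scope="session")
def paired_small():
    """Small paired-treatment simulation shared across tests."""
    return ps.make_paired_treatments(ps.SimConfig(n_groups=25, seed=101))


@pytest.fixture(scope="session")
def paired_summaries(paired_small):
    out = {}
    for name, ds in paired_small.items():
        out[name] = ps.summaries_to_frame(
            ps.compute_male_summaries(ds.events, ds.paternity, ds.rosters)
        )
    return out


@pytest.fixture()
def tiny_dataset():
    """Hand-built one-group dataset with known summary values.

    Focal mates female A twice and B once; A produced 10 daughters (6 by
    the focal), B produced 5 (1 by the focal).  A rival mated B and C; C
    produced 4 daughters, none by the focal.
    """
    roster = ps.GroupRoster(
        group_id="g1",
        treatment="control",
        males=(("m_focal", "focal"), ("m_r1", "rival"), ("m_r2", "rival")),
        females=("fA", "fB", "fC"),
        replicate_id="R1",
    )
    ev = [
        ps.MatingEvent("g1", "R1", "control", 1, 1, "m_focal", "fA"),
        ps.MatingEvent("g1", "R1", "control", 1, 2, "m_r1", "fB"),
        ps.MatingEvent("g1", "R1", "control", 2, 1, "m_focal", "fB"),
        ps.MatingEvent("g1", "R1", "control", 2, 2, "m_focal", "fA"),
        ps.MatingEvent("g1", "R1", "control", 3, 1, "m_r1", "fC"),
    ]
    pat = [
        ps.PaternityRecord("g1", "fA", 6, 4),
        ps.PaternityRecord("g1", "fB", 1, 4),
        ps.PaternityRecord("g1", "fC", 0, 4),
    ]
    return ev, pat, {"g1": roster}


def make_summaries_frame(T, M, P, N, **extra) -> pd.DataFrame:
    """Summary-table scaffold for statistics-level tests."""
    n = len(T)
    df = pd.DataFrame(
        {
            "male_id": [f"m{i}" for i in range(n)],
            "group_id": [f"g{i}" for i in range(n)],
            "treatment": extra.pop("treatment", ["t"] * n),
            "replicate_id": extra.pop("replicate_id", ["R1", "R2"] * (n // 2) + ["R1"] * (n % 2)),
            "mating_frequency": M,
            "M": M,
            "repetitive_rate": extra.pop("repetitive_rate", [1.0] * n),
            "N": N,
            "P": P,
            "T": T,
            "group_fecundity": extra.pop("group_fecundity", [50.0] * n),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
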