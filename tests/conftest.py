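import numpy as np
import pandas as pd
import pytest

from aorweb.seq_delim import SequenceRecord


def make_records(groups: dict[str, list[str]], pu_map=None, site="S01",
                 island="I1") -> list[SequenceRecord]:
    """Build records from {individual_id: sequence} style groups:
    groups maps pu -> list of sequences."""
    records = []
    for pu, seqs in groups.items():
        for i, seq in enumerate(seqs):
            records.append(
                SequenceRecord(
                    individual_id=f"{pu}_{i + 1}",
                    sequence=seq,
                    pu=pu if pu_map is None else pu_map.get(pu, pu),
                    site=site,
                    island=island,
                )
            )
    return records


def mutate(seq: str, positions: list[int], bases: str) -> str:
    s = list(seq)
    for pos, b in zip(positions, bases):
        s[pos] = b
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(20230051)


@pytest.fixture
def base_seq():
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), size=200))


@pytest.fixture
def random_distance_matrix():
    def make(n: int, rng: np.random.Generator) -> np.ndarray:
        d = rng.uniform(0.005, 0.3, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return d

    return make


@pytest.fixture
def aor_table(rng):
    """Small species table with a known logistic occupancy structure."""
    n = 120
    dispersal = np.where(rng.random(n) < 0.5, "ballooning", "non-ballooning")
    lam = rng.lognormal(1.2, 1.0, n)
    coefs = {"ballooning": (-2.0, 1.5), "non-ballooning": (-3.0, 2.0)}
    total = 31
    b = np.array([coefs[d] for d in dispersal])
    p = 1 / (1 + np.exp(-(b[:, 0] + b[:, 1] * np.log(lam))))
    occ = rng.binomial(total, p)
    keep = occ > 0
    return pd.DataFrame(
        {
            "species": [f"SP{i:03d}" for i in range(n)],
            "dispersal": dispersal,
            "log_abundance": np.log(lam),
            "occupied_sites": occ,
            "total_sites": total,
        }
    )[keep].reset_index(drop=True)
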