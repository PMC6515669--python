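import random

import pytest

from mgecds import MatchRecord
from mgecds.synth import PlantSpec, generate, truth_domain_hits, truth_matches


@pytest.fixture(scope="session")
def fixture_suite():
    """The standard 50-element planted suite: assembly, truth, matches."""
    spec = PlantSpec(seed=20190514)
    assembly, truth = generate(spec)
    return {
        "spec": spec,
        "assembly": assembly,
        "truth": truth,
        "matches": truth_matches(truth),
    }


@pytest.fixture(scope="session")
def hits_at_2000(fixture_suite):
    return truth_domain_hits(fixture_suite["truth"], 2000)


def random_matches(rng: random.Random, n_max: int = 200) -> list[MatchRecord]:
    """Random match sets over a couple of contigs, for merge oracles."""
    n = rng.randint(1, n_max)
    out = []
    for _ in range(n):
        contig = rng.choice(["c1", "c2", "c3"])
        start = rng.randint(0, 50_000)
        length = rng.randint(1, 3000)
        out.append(
            MatchRecord(
                contig_id=contig,
                start=start,
                end=start + length,
                strand=rng.choice("+-"),
                repeat_name=f"r{_}",
            )
        )
    return out


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
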