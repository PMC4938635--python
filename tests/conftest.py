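import numpy as np
import pytest

import dsxmodes as dm


@pytest.fixture(scope="session")
def worked_fixture():
    """The deterministic 18-gene miniature (delta=3 ln units, sigma=0.1)."""
    return dm.make_worked_fixture()


@pytest.fixture(scope="session")
def fixture_run(worked_fixture):
    """Full pipeline result on the worked fixture."""
    sim = worked_fixture
    return dm.analyze(sim.regions, sim.counts, sim.meta, sim.annotations)


def random_gene_model(rng: np.random.Generator, gene_id: str, max_exons: int = 50):
    """A randomized multi-isoform gene model with small coordinates.

    Small coordinates keep the per-base oracle cheap; exon boundaries are
    drawn freely so identical, nested, staggered, and disjoint exon pairs
    all occur.
    """
    n_iso = int(rng.integers(1, 4))
    total = 0
    transcripts = []
    for t in range(n_iso):
        n_exons = int(rng.integers(1, max(2, max_exons // n_iso)))
        total += n_exons
        exons = []
        for _ in range(n_exons):
            start = int(rng.integers(0, 3000))
            end = start + int(rng.integers(1, 400))
            exons.append((start, end))
        transcripts.append((f"{gene_id}.t{t+1}", tuple(exons)))
    return dm.GeneModel(gene_id, "chr2L", "+", tuple(transcripts))


def per_base_region_oracle(model):
    """Independent oracle: connected components of the exon-overlap graph.

    Distinct exon footprints sharing at least one base are linked; each
    component yields one region spanning its footprints, classed single iff
    it holds exactly one distinct footprint.
    """
    footprints = sorted(set(model.all_exons))
    n = len(footprints)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = footprints[i], footprints[j]
            if set(range(s1, e1)) & set(range(s2, e2)):
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(footprints[i])
    out = set()
    for members in comps.values():
        start = min(s for s, _ in members)
        end = max(e for _, e in members)
        cls = "single" if len(members) == 1 else "overlap"
        out.add((start, end, cls))
    return out
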