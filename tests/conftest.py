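import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from uccomics.genome_catalog import Gene, MemberGenome


def make_genome(genome_id, contig_lens, genes=(), seed=0, taxon="Gammaproteobacteria"):
    """Small random genome; genes given as (gene_id, contig_id, start, end, labels)."""
    rng = np.random.default_rng(seed)
    contigs = {
        cid: "".join(rng.choice(list("ACGT"), size=n)) for cid, n in contig_lens.items()
    }
    gene_objs = [
        Gene(gid, genome_id, cid, start, end, marker_labels=set(labels))
        for gid, cid, start, end, labels in genes
    ]
    return MemberGenome(genome_id=genome_id, contigs=contigs, genes=gene_objs, taxon_group=taxon)


@pytest.fixture
def two_genome_catalog():
    """genomeA: one 100 bp contig; genomeB: one 200 bp contig (spacer fixture)."""
    a = make_genome("genomeA", {"contig1": 100}, [("gA1", "contig1", 1, 60, ["pstS"])], seed=1)
    b = make_genome("genomeB", {"contig1": 200}, [("gB1", "contig1", 41, 160, [])], seed=2)
    return [a, b]


@pytest.fixture(scope="session")
def default_sim():
    from uccomics import simulate_community

    return simulate_community(seed=0)
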