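import numpy as np
import pandas as pd
import pytest

from popkit import (
    BiallelicMatrix,
    CallSet,
    DepthTrack,
    GroupSpec,
    PopulationModel,
    simulate_populations,
)


def make_callset(rows, accession="acc", caller="caller"):
    """rows: iterable of (chrom, pos, ref, alt, alt_reads, depth)."""
    rec = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_reads", "depth"])
    return CallSet(accession, caller, rec)


def make_matrix(genotypes, positions=None, chrom="chr1", names=None):
    G = np.asarray(genotypes, dtype=np.int8)
    n, m = G.shape
    pos = positions if positions is not None else np.arange(1, m + 1) * 100
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})
    names = names or [f"s{i}" for i in range(n)]
    return BiallelicMatrix(names, sites, G)


def full_depth(accession, chrom_lengths, depth=50):
    return DepthTrack(
        accession, {c: np.full(int(n), depth, dtype=np.int32) for c, n in chrom_lengths.items()}
    )


@pytest.fixture
def two_group_model():
    return PopulationModel(
        chromosome_lengths=(300_000,),
        n_sites=300,
        groups=(GroupSpec("a", 6, 0.3), GroupSpec("b", 6, 0.3)),
        admixed=(("mix_1", {"a": 0.5, "b": 0.5}),),
        seed=7,
    )


@pytest.fixture
def two_group_truth(two_group_model):
    return simulate_populations(two_group_model)
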