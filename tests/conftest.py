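import numpy as np
import pytest

from microttr import CommunityTable, TaxonomyMap


def make_table(counts, sample_prefix="s", taxa=None, times=None):
    counts = np.asarray(counts)
    n, p = counts.shape
    return CommunityTable(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        sample_times=list(times) if times is not None else list(range(1, n + 1)),
        taxon_ids=list(taxa) if taxa is not None else [f"t{j}" for j in range(p)],
        counts=counts,
    )


def presence_table(taxon_sets):
    """Table from per-sample presence sets; present taxa get count 1."""
    taxa = sorted({t for s in taxon_sets for t in s})
    counts = np.array(
        [[1 if t in s else 0 for t in taxa] for s in taxon_sets], dtype=np.int64
    )
    return make_table(counts, taxa=taxa)


def flat_taxonomy(taxon_ids, phylum_of=None):
    """One-level taxonomy: every rank repeats the phylum (or the taxon id)."""
    entries = {}
    for t in taxon_ids:
        name = phylum_of[t] if phylum_of else t
        entries[t] = {r: name for r in ("phylum", "class", "order", "family", "genus")}
    return TaxonomyMap(entries=entries)


@pytest.fixture
def toy_table():
    return make_table([[3, 4, 0], [1, 2, 5], [2, 2, 2]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
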