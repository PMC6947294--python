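import pytest

from phylostress.taxonomy import Lineage, Phylostratum


@pytest.fixture(scope="session")
def deep_lineage():
    """18-level lineage, ranks 0..17, focal species in the terminal stratum."""
    strata = []
    for r in range(18):
        species = {f"sp{r}a", f"sp{r}b"} if r < 17 else {"focal", "sp17a"}
        strata.append(Phylostratum(name=f"L{r:02d}", rank=r, species=frozenset(species)))
    return Lineage(tuple(strata), focal_species="focal")


@pytest.fixture(scope="session")
def small_lineage():
    """5-level lineage for hand-checkable examples."""
    strata = [
        Phylostratum("root", 0, {"s0"}),
        Phylostratum("mid1", 1, {"s1"}),
        Phylostratum("mid2", 2, {"s2a", "s2b"}),
        Phylostratum("mid3", 3, {"s3"}),
        Phylostratum("tip", 4, {"focal"}),
    ]
    return Lineage(tuple(strata), focal_species="focal")
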