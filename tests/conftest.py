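import numpy as np
import pytest

from httflow.core_io import CodonAlignment, SpeciesTree, write_codon_alignment


@pytest.fixture(scope="session")
def two_species_tree() -> SpeciesTree:
    """Two lineages split 15 Mya (reference mean dS ~ 0.6 at r = 0.02)."""
    return SpeciesTree.from_newick("(A:15,B:15);")


@pytest.fixture(scope="session")
def five_species_tree() -> SpeciesTree:
    from httflow.core_io import demo_tree

    return demo_tree()


@pytest.fixture()
def toy_alignment(tmp_path):
    """5 species x 300 bp (100 codon columns) written to a FASTA file."""
    rng = np.random.default_rng(42)
    codons = [
        "".join(rng.choice(list("ACGT"), 3))
        for _ in range(100)
    ]
    # avoid stop codons in the shared backbone
    codons = [c if c not in {"TAA", "TAG", "TGA"} else "TTA" for c in codons]
    base = "".join(codons)
    sequences = {}
    for i, sp in enumerate(["BM", "BD", "IV", "IC", "LT"]):
        seq = list(base)
        for pos in rng.integers(0, 100, size=3 * i):  # a few species differences
            seq[3 * pos + 2] = "T"
        sequences[sp] = "".join(seq)
    aln = CodonAlignment(id="toy", sequences=sequences)
    path = tmp_path / "toy.fasta"
    write_codon_alignment(aln, path)
    return path, aln
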