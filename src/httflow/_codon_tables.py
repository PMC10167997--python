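"""Codon-level lookup tables shared by the divergence statistics and the simulator.

Codons are encoded as integers ``16*b1 + 4*b2 + b3`` with A,C,G,T -> 0..3.
Anything else (gaps, ambiguity codes) encodes as -1 and is excluded pairwise
by the callers.

The Nei-Gojobori quantities are precomputed once per interpreter:

* ``SYN_SITES[c]``   fractional number of synonymous sites of codon ``c``
  (per position, the fraction of the three single-nucleotide changes that
  preserve the amino acid; mutations to stop codons count as nonsynonymous);
* ``SYN_DIFFS[a, b]`` average number of synonymous differences between codons
  ``a`` and ``b`` over all shortest mutational pathways, pathways through stop
  codons excluded when at least one stop-free pathway exists.

These make pairwise dS on integer codon arrays a pure table lookup, which is
what keeps the Monte-Carlo calibrations cheap.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: codon strings in integer-encoding order (AAA, AAC, ..., TTT)
CODONS: list[str] = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code

#: amino acid per codon; '*' marks stops
AMINO_ACIDS: list[str] = [
    "*" if c in _table.stop_codons else _table.forward_table[c] for c in CODONS
]

IS_STOP = np.array([aa == "*" for aa in AMINO_ACIDS])


def encode_codons(seq: str) -> np.ndarray:
    """Encode a nucleotide string into an int array of codons (-1 = unusable).

    ``seq`` must have length divisible by 3. Codons containing gaps,
    ambiguity codes or lowercase-normalized non-ACGT characters map to -1.
    """
    s = seq.upper()
    if len(s) % 3:
        raise ValueError(f"sequence length {len(s)} not divisible by 3")
    n = len(s) // 3
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = s[3 * i : 3 * i + 3]
        try:
            out[i] = (
                16 * _BASE_INDEX[c[0]] + 4 * _BASE_INDEX[c[1]] + _BASE_INDEX[c[2]]
            )
        except KeyError:
            out[i] = -1
    return out


def decode_codons(codons: np.ndarray) -> str:
    return "".join("---" if c < 0 else CODONS[c] for c in codons)


def _single_changes(codon_idx: int) -> list[tuple[int, int]]:
    """All (position, target codon index) single-nucleotide neighbours."""
    c = CODONS[codon_idx]
    out = []
    for pos in range(3):
        for b in BASES:
            if b != c[pos]:
                out.append((pos, CODON_INDEX[c[:pos] + b + c[pos + 1 :]]))
    return out


def _build_syn_sites() -> np.ndarray:
    s = np.zeros(64)
    for i in range(64):
        if IS_STOP[i]:
            continue
        syn = 0
        for _, j in _single_changes(i):
            if not IS_STOP[j] and AMINO_ACIDS[j] == AMINO_ACIDS[i]:
                syn += 1
        s[i] = syn / 3.0
    return s


SYN_SITES = _build_syn_sites()


def _pathway_counts(a: int, b: int) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between codons a, b."""
    diff_pos = [p for p in range(3) if CODONS[a][p] != CODONS[b][p]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            target_base = CODONS[b][pos]
            cur_str = CODONS[cur]
            nxt = CODON_INDEX[cur_str[:pos] + target_base + cur_str[pos + 1 :]]
            if IS_STOP[nxt] or IS_STOP[cur]:
                through_stop = True
                nonsyn += 1
            elif AMINO_ACIDS[cur] == AMINO_ACIDS[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        results.append((through_stop, syn, nonsyn))
    clean = [(s, n) for stop, s, n in results if not stop]
    if not clean:  # every pathway crosses a stop; average over all of them
        clean = [(s, n) for _, s, n in results]
    syn = sum(s for s, _ in clean) / len(clean)
    nonsyn = sum(n for _, n in clean) / len(clean)
    return syn, nonsyn


def _build_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    syn = np.zeros((64, 64))
    nonsyn = np.zeros((64, 64))
    for a in range(64):
        for b in range(a + 1, 64):
            s, n = _pathway_counts(a, b)
            syn[a, b] = syn[b, a] = s
            nonsyn[a, b] = nonsyn[b, a] = n
    return syn, nonsyn


SYN_DIFFS, NONSYN_DIFFS = _build_diff_tables()

# ---------------------------------------------------------------------------
# Degeneracy families for Wright's effective number of codons.
# ---------------------------------------------------------------------------

#: amino acid -> list of codon indices (sense codons only)
FAMILIES: dict[str, list[int]] = {}
for i, aa in enumerate(AMINO_ACIDS):
    if aa != "*":
        FAMILIES.setdefault(aa, []).append(i)

#: degeneracy class (family size) per amino acid
FAMILY_SIZE: dict[str, int] = {aa: len(v) for aa, v in FAMILIES.items()}

#: Wright's composition of the standard code: counts of families per class
FAMILY_CLASS_COUNTS: dict[int, int] = {}
for aa, k in FAMILY_SIZE.items():
    FAMILY_CLASS_COUNTS[k] = FAMILY_CLASS_COUNTS.get(k, 0) + 1
# standard code: {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}

#: codon index -> family id (position of its amino acid in sorted order), -1 for stops
_AA_SORTED = sorted(FAMILIES)
FAMILY_ID = np.full(64, -1, dtype=np.int64)
for fid, aa in enumerate(_AA_SORTED):
    for c in FAMILIES[aa]:
        FAMILY_ID[c] = fid

# ---------------------------------------------------------------------------
# Synonymous single-nucleotide neighbours (used by the simulator).
# ---------------------------------------------------------------------------

_MAX_NBR = 4  # no sense codon has more than 4 synonymous single-nt neighbours


def _build_syn_neighbours() -> np.ndarray:
    nbr = np.full((64, _MAX_NBR), -1, dtype=np.int64)
    for i in range(64):
        if IS_STOP[i]:
            continue
        js = [
            j
            for _, j in _single_changes(i)
            if not IS_STOP[j] and AMINO_ACIDS[j] == AMINO_ACIDS[i]
        ]
        nbr[i, : len(js)] = js
    return nbr


SYN_NEIGHBOURS = _build_syn_neighbours()

#: preferred codon per family: lowest codon index (alphabetically first)
PREFERRED = np.zeros(len(_AA_SORTED), dtype=np.int64)
for fid, aa in enumerate(_AA_SORTED):
    PREFERRED[fid] = min(FAMILIES[aa])


def codon_bias_weights(b: float) -> np.ndarray:
    """Per-codon sampling weight under bias strength ``b`` in [0, 1].

    Within each synonymous family of size k the preferred codon has weight
    ``b + (1-b)/k`` and the others ``(1-b)/k``; at b=0 usage is uniform, at
    b=1 only the preferred codon is used. Stop codons get weight 0.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    w = np.zeros(64)
    for aa, codons in FAMILIES.items():
        k = len(codons)
        for c in codons:
            w[c] = (1.0 - b) / k
        w[min(codons)] += b
    return w
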