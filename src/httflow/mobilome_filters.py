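"""Post-processing of homology hits and TE copy sets.

Covers the bookkeeping between raw homology searches and the codon-level
analysis: bit-score/length filtering with deterministic best-hit selection,
CD-HIT-like greedy redundancy clustering, majority-rule consensus building,
and Kimura two-parameter divergence landscapes (copy-to-consensus distance
histograms whose shape distinguishes recent transposition bursts from older,
episodic activity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import HitRecord
from .divergence_stats import percent_identity

logger = logging.getLogger("httflow")

TE_ORDERS = {"LTR", "LINE", "SINE", "TIR", "Crypton", "Helitron", "Maverick", "Unknown"}

#: landscape x-axis cap (substitutions/site); saturated distances are excluded
LANDSCAPE_DMAX = 0.5


class SaturatedDistanceError(ArithmeticError):
    """K2P distance undefined: substitution fractions beyond the model range."""


@dataclass
class TECopySet:
    """Aligned copies of one TE family, optionally with a consensus."""

    superfamily: str
    order: str
    copies: list[tuple[str, str]]  # (species id, aligned sequence)
    consensus: str | None = None

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError(f"{self.superfamily}: empty copy set")
        if self.order not in TE_ORDERS:
            raise ValueError(f"unknown TE order {self.order!r}")


@dataclass
class LandscapeBin:
    lower: float
    upper: float
    #: superfamily -> relative frequency within this bin
    frequencies: dict[str, float] = field(default_factory=dict)


def filter_hits(
    hits: list[HitRecord],
    min_bitscore: float = 160.0,
    min_len: int = 130,
) -> list[HitRecord]:
    """Threshold filter plus deterministic best-hit selection per query.

    A hit is retained iff ``bitscore >= min_bitscore`` and
    ``length >= min_len``; among a query's surviving hits only the best
    bit-score one is kept, ties broken by longest alignment and then
    lexicographic subject id. Idempotent and invariant to input order.
    """
    if min_bitscore <= 0 or min_len <= 0:
        raise ValueError("thresholds must be positive")
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.bitscore < min_bitscore or h.length < min_len:
            continue
        cur = best.get(h.query)
        if cur is None or (h.bitscore, h.length, _neg_lex(h.subject)) > (
            cur.bitscore, cur.length, _neg_lex(cur.subject)
        ):
            best[h.query] = h
    return [best[q] for q in sorted(best)]


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def greedy_cluster(
    seqs: list[str], id_threshold: float = 0.95
) -> list[list[int]]:
    """CD-HIT-like greedy clustering by global identity.

    Sequences are sorted by length (descending; ties by original index for
    determinism). Each sequence joins the first existing cluster whose
    representative (founder) it matches at more than ``id_threshold`` global
    identity, otherwise it founds a new cluster. Returns clusters as lists of
    indices into ``seqs``.
    """
    if not 0 < id_threshold <= 1:
        raise ValueError("id_threshold must be in (0, 1]")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    clusters: list[list[int]] = []
    for i in order:
        placed = False
        for cluster in clusters:
            rep = seqs[cluster[0]]
            if _global_identity(rep, seqs[i]) > id_threshold:
                cluster.append(i)
                placed = True
                break
        if not placed:
            clusters.append([i])
    return clusters


def _global_identity(a: str, b: str) -> float:
    """Global identity: matches over the longer sequence length.

    Pre-aligned equal-length inputs reduce to column identity; unaligned
    inputs are compared position-wise against the longer length, which is
    the conservative CD-HIT-style global (not local) convention.
    """
    if len(a) == len(b):
        return percent_identity(a, b)
    short, long_ = sorted((a, b), key=len)
    matches = sum(1 for x, y in zip(short.upper(), long_.upper()) if x == y and x != "-")
    return matches / len(long_)


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between equal-length sequences.

    Sites where either sequence has a gap or ambiguity code are excluded.
    ``d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`` with P, Q the transition and
    transversion fractions. Raises :class:`SaturatedDistanceError` when the
    logarithm's argument is non-positive and ``ValueError`` with zero
    comparable sites.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    purines = {"A", "G"}
    transitions = transversions = comparable = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        comparable += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            transitions += 1
        else:
            transversions += 1
    if comparable == 0:
        raise ValueError("no comparable sites")
    p = transitions / comparable
    q = transversions / comparable
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(f"saturated: P={p:.3f}, Q={q:.3f}")
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def build_consensus(copies: TECopySet) -> str:
    """Per-column majority-rule consensus over aligned copies.

    Ties are broken by the fixed base order A < C < G < T; columns with more
    than 50% gaps are dropped.
    """
    seqs = [s.upper() for _, s in copies.copies]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("copies must be aligned to equal length")
    out = []
    half = len(seqs) / 2.0
    for col in range(length):
        column = [s[col] for s in seqs]
        n_gaps = sum(1 for c in column if c not in "ACGT")
        if n_gaps > half:
            continue
        counts: dict[str, int] = {}
        for c in column:
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        best = max(counts, key=lambda base: (counts[base], -"ACGT".index(base)))
        out.append(best)
    return "".join(out)


def build_landscape(
    copy_sets: list[TECopySet], bin_width: float = 0.01
) -> list[LandscapeBin]:
    """K2P copy-to-consensus divergence histogram per superfamily.

    Each copy contributes its distance to the family consensus to one bin;
    frequencies are normalized to 1 within each superfamily. Saturated or
    out-of-range distances (> :data:`LANDSCAPE_DMAX`) are excluded and
    counted in the log.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, LANDSCAPE_DMAX + bin_width, bin_width)
    per_sf: dict[str, np.ndarray] = {}
    n_excluded = 0
    for cs in copy_sets:
        consensus = cs.consensus or build_consensus(cs)
        hist = per_sf.setdefault(cs.superfamily, np.zeros(len(edges) - 1))
        for _, seq in cs.copies:
            try:
                d = k2p_distance(seq, consensus)
            except (SaturatedDistanceError, ValueError):
                n_excluded += 1
                continue
            if d >= LANDSCAPE_DMAX:
                n_excluded += 1
                continue
            hist[min(int(d / bin_width), len(hist) - 1)] += 1
    if n_excluded:
        logger.info("landscape: %d saturated/out-of-range copies excluded", n_excluded)
    bins = [
        LandscapeBin(lower=float(edges[i]), upper=float(edges[i + 1]))
        for i in range(len(edges) - 1)
    ]
    for sf, hist in per_sf.items():
        total = hist.sum()
        if total == 0:
            continue
        freqs = hist / total
        for i, f in enumerate(freqs):
            bins[i].frequencies[sf] = float(f)
    return bins


def landscape_frame(bins: list[LandscapeBin]) -> pd.DataFrame:
    """Plot-ready long-format table (superfamily, bin bounds, frequency)."""
    rows = []
    for b in bins:
        for sf, f in sorted(b.frequencies.items()):
            rows.append([sf, b.lower, b.upper, f])
    return pd.DataFrame(rows, columns=["superfamily", "lower", "upper", "frequency"])
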