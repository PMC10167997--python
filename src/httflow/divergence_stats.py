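"""Synonymous divergence (Nei-Gojobori dS) and codon usage bias (Wright's ENC).

These are the two axes of the horizontal-transfer contrast: dS measures
neutral divergence between a pair of sequences, ENC measures how biased each
sequence's synonymous codon usage is (20 = one codon per amino acid,
61 = uniform usage). Because dS and ENC covary in vertically inherited genes,
a transposable element transferred between species stands out as a point with
far lower dS than reference genes of similar ENC.

Conventions (recorded in output metadata by the pipeline):

* dS is the Nei-Gojobori (1986) estimator with equal weighting of shortest
  mutational pathways and the Jukes-Cantor correction
  ``dS = -(3/4) ln(1 - (4/3) pS)``;
* codons containing gaps or ambiguity codes in either sequence of a pair are
  excluded pairwise;
* ENC is Wright's (1990) statistic
  ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` with family homozygosities averaged
  within degeneracy classes; families observed fewer than twice are imputed
  from their class mean; the result is clipped to [20, 61].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._codon_tables import (
    FAMILY_CLASS_COUNTS,
    FAMILY_ID,
    FAMILY_SIZE,
    IS_STOP,
    SYN_DIFFS,
    SYN_SITES,
    _AA_SORTED,
    encode_codons,
)
from .core_io import CodonAlignment

#: pS at which the Jukes-Cantor correction diverges
_SATURATION_PS = 0.75

MIN_COMPARABLE_CODONS = 10


class SaturationError(ArithmeticError):
    """Synonymous divergence beyond the correctable range (pS >= 3/4)."""


@dataclass
class GeneStats:
    """Pairwise codon statistics for one alignment and one species pair."""

    alignment_id: str
    species_pair: tuple[str, str]
    ds: float
    syn_sites: float
    syn_diffs: float
    n_codons: int
    enc: tuple[float, float]
    saturated: bool = False

    @property
    def mean_enc(self) -> float:
        return 0.5 * (self.enc[0] + self.enc[1])


def _comparable(codons_a: np.ndarray, codons_b: np.ndarray) -> np.ndarray:
    """Mask of codon columns usable in both sequences (no gap/N/stop)."""
    ok = (codons_a >= 0) & (codons_b >= 0)
    ok &= ~IS_STOP[np.clip(codons_a, 0, 63)] & ~IS_STOP[np.clip(codons_b, 0, 63)]
    return ok


def ds_from_codon_arrays(
    codons_a: np.ndarray, codons_b: np.ndarray
) -> tuple[float, float, float, int]:
    """Return (dS, synonymous sites S, synonymous differences, n codons).

    Raises :class:`SaturationError` when pS >= 3/4 and ``ValueError`` when no
    synonymous sites remain.
    """
    ok = _comparable(codons_a, codons_b)
    a, b = codons_a[ok], codons_b[ok]
    n = int(ok.sum())
    s_sites = float(0.5 * (SYN_SITES[a] + SYN_SITES[b]).sum())
    if s_sites <= 0:
        raise ValueError("no synonymous sites in comparable codons")
    s_diffs = float(SYN_DIFFS[a, b].sum())
    ps = s_diffs / s_sites
    if ps >= _SATURATION_PS:
        raise SaturationError(f"pS = {ps:.3f} >= 3/4: divergence saturated")
    ds = -0.75 * np.log1p(-4.0 / 3.0 * ps)
    return float(ds), s_sites, s_diffs, n


def compute_ds(aln: CodonAlignment, sp1: str, sp2: str) -> float:
    """Nei-Gojobori synonymous distance between two species of an alignment.

    Symmetric in its arguments. Requires at least
    :data:`MIN_COMPARABLE_CODONS` gap-free codons in both sequences.
    """
    for sp in (sp1, sp2):
        if sp not in aln.sequences:
            raise KeyError(f"{aln.id}: species {sp!r} not in alignment")
    a = encode_codons(aln.sequences[sp1])
    b = encode_codons(aln.sequences[sp2])
    if int(_comparable(a, b).sum()) < MIN_COMPARABLE_CODONS:
        raise ValueError(
            f"{aln.id}: fewer than {MIN_COMPARABLE_CODONS} comparable codons "
            f"for pair ({sp1}, {sp2})"
        )
    ds, _, _, _ = ds_from_codon_arrays(a, b)
    return ds


def enc_from_codon_array(codons: np.ndarray) -> float:
    """Wright's effective number of codons from an integer codon array."""
    codons = codons[codons >= 0]
    codons = codons[~IS_STOP[codons]]
    if codons.size == 0:
        raise ValueError("empty sequence: ENC undefined")
    counts = np.bincount(codons, minlength=64)

    # per-family homozygosity F = (n * sum p^2 - 1) / (n - 1)
    class_f: dict[int, list[float]] = {k: [] for k in FAMILY_CLASS_COUNTS}
    for fid, aa in enumerate(_AA_SORTED):
        k = FAMILY_SIZE[aa]
        if k == 1:
            continue  # Met, Trp contribute the constant 2
        fam_counts = counts[FAMILY_ID == fid]
        n = int(fam_counts.sum())
        if n < 2:
            continue
        p = fam_counts / n
        f = (n * float((p**2).sum()) - 1.0) / (n - 1.0)
        if f > 0:
            class_f[k].append(f)

    def mean_f(k: int) -> float | None:
        return float(np.mean(class_f[k])) if class_f[k] else None

    f2, f3, f4, f6 = (mean_f(k) for k in (2, 3, 4, 6))
    # the 3-fold class has a single family (Ile); impute from neighbours
    if f3 is None and f2 is not None and f4 is not None:
        f3 = 0.5 * (f2 + f4)
    available = [f for f in (f2, f3, f4, f6) if f is not None]
    if not available:
        raise ValueError("too few codons to estimate any family homozygosity")
    fallback = float(np.mean(available))
    f2 = fallback if f2 is None else f2
    f3 = fallback if f3 is None else f3
    f4 = fallback if f4 is None else f4
    f6 = fallback if f6 is None else f6

    enc = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return float(np.clip(enc, 20.0, 61.0))


def compute_enc(seq: str) -> float:
    """Wright's ENC of one codon sequence (gaps/stops excluded)."""
    return enc_from_codon_array(encode_codons(seq))


def percent_identity(a: str, b: str) -> float:
    """Fraction of matching positions among comparable ones.

    Positions gapped in both sequences are excluded; positions gapped in
    exactly one sequence count as mismatches.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    a, b = a.upper(), b.upper()
    matches = comparable = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        comparable += 1
        if x == y and x != "-":
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable positions")
    return matches / comparable


def pair_stats(aln: CodonAlignment, sp1: str, sp2: str) -> GeneStats:
    """Full dS/ENC record for one species pair; saturation sets a flag
    (ds = inf) instead of raising."""
    a = encode_codons(aln.sequences[sp1])
    b = encode_codons(aln.sequences[sp2])
    enc = (enc_from_codon_array(a), enc_from_codon_array(b))
    ok = _comparable(a, b)
    try:
        ds, s_sites, s_diffs, n = ds_from_codon_arrays(a, b)
        saturated = False
    except SaturationError:
        ds, saturated = float("inf"), True
        s_sites = float(0.5 * (SYN_SITES[a[ok]] + SYN_SITES[b[ok]]).sum())
        s_diffs = float(SYN_DIFFS[a[ok], b[ok]].sum())
        n = int(ok.sum())
    return GeneStats(
        alignment_id=aln.id,
        species_pair=(sp1, sp2),
        ds=ds,
        syn_sites=s_sites,
        syn_diffs=s_diffs,
        n_codons=n,
        enc=enc,
        saturated=saturated,
    )
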