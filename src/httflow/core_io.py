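"""Readers/writers, domain containers, run configuration and packaged fixtures.

External formats handled here: codon-aligned FASTA, newick species trees,
BLAST-style tab-separated hit tables, CSV incidence fixtures, ESRI ASCII /
headerless-CSV suitability grids, and YAML run configuration. Tabular
intermediate results (signals, events) travel as pandas DataFrames and plain
TSV throughout the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("httflow")

#: two-letter codes of the five flower-breeding Drosophila species, in the
#: column order used by the packaged incidence fixture
FBD_SPECIES = ["BM", "BD", "IV", "IC", "LT"]

#: unordered species-pair column labels in fixture order
FBD_PAIRS = [
    "BMxBD", "BMxIV", "BMxIC", "BMxLT", "BDxIV",
    "BDxIC", "BDxLT", "IVxIC", "IVxLT", "ICxLT",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """A codon-aware multiple alignment, one sequence per species.

    Parameters
    ----------
    id:
        Gene or TE-family identifier.
    sequences:
        Mapping species id -> aligned sequence (uppercase DNA plus ``-``
        gaps). All sequences must have equal length divisible by 3.
    annotation:
        Free-form metadata; the pipeline uses the keys ``kind``
        (``"reference"`` or ``"te"``), ``superfamily`` and ``order``.
    """

    id: str
    sequences: dict[str, str]
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError(f"{self.id}: empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise FormatError(f"{self.id}: unequal sequence lengths {lengths}")
        (length,) = lengths
        if length % 3:
            raise FormatError(
                f"{self.id}: alignment length {length} not divisible by 3"
            )
        self.sequences = {
            sp: seq.upper() for sp, seq in self.sequences.items()
        }

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def pairs(self) -> list[tuple[str, str]]:
        sp = self.species
        return [(a, b) for i, a in enumerate(sp) for b in sp[i + 1 :]]


def species_from_header(header: str, delimiter: str = "|") -> str:
    """Species id = header token before the first delimiter (default ``|``)."""
    return header.split(delimiter, 1)[0]


def read_codon_alignment(
    path: str | Path, *, id: str | None = None, delimiter: str = "|"
) -> CodonAlignment:
    """Read a codon-aligned FASTA file into a :class:`CodonAlignment`.

    Species ids are parsed from record headers as the token before the first
    ``delimiter``. Duplicate species or ragged/non-codon lengths raise
    :class:`FormatError`.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = species_from_header(rec.id, delimiter)
        if sp in sequences:
            raise FormatError(f"{path.name}: duplicate species id {sp!r}")
        sequences[sp] = str(rec.seq)
    if not sequences:
        raise FormatError(f"{path.name}: no FASTA records")
    return CodonAlignment(id=id or path.stem, sequences=sequences)


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="")
        for sp, seq in aln.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


class SpeciesTree:
    """Ultrametric, dated species tree (ages in Myr before present).

    Wraps a :class:`dendropy.Tree`; node ages are computed from root-to-tip
    path lengths. Non-ultrametric input (leaf depths differing by more than
    ``rel_tol`` of tree depth) triggers a warning and best-fit ages
    (node age = mean tip depth below the node minus node depth).
    """

    def __init__(self, tree: dendropy.Tree, rel_tol: float = 1e-6):
        self._tree = tree
        tree.is_rooted = True
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = tree.leaf_node_iter()
        depths = {lf.taxon.label: lf.root_distance for lf in leaves}
        if not depths:
            raise FormatError("tree has no leaves")
        if len(depths) != len(set(depths)):
            raise FormatError("duplicate leaf labels")
        self.taxa = sorted(depths)
        self.depth = max(depths.values())
        spread = self.depth - min(depths.values())
        self.ultrametric = spread <= rel_tol * max(self.depth, 1.0)
        if not self.ultrametric:
            logger.warning(
                "tree is not ultrametric (leaf-depth spread %.3g); "
                "best-fit node ages assigned", spread,
            )
        self._ages: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                self._ages[id(node)] = 0.0
            else:
                tip_depths = [
                    lf.root_distance for lf in node.leaf_iter()
                ]
                self._ages[id(node)] = float(
                    np.mean(tip_depths) - node.root_distance
                )

    @classmethod
    def from_newick(cls, newick: str, **kw) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, **kw)

    def _leaf(self, label: str) -> dendropy.Node:
        taxon = self._tree.taxon_namespace.get_taxon(label)
        if taxon is None:
            raise KeyError(f"species {label!r} not in tree")
        return self._tree.find_node_with_taxon_label(label)

    def mrca_age(self, a: str, b: str) -> float:
        """Age (Mya) of the most recent common ancestor of leaves a, b."""
        if a == b:
            self._leaf(a)
            return 0.0
        mrca = self._tree.mrca(taxon_labels=[a, b])
        if mrca is None:
            raise KeyError(f"no MRCA for {a!r}, {b!r}")
        return self._ages[id(mrca)]

    def is_sister(self, a: str, b: str) -> bool:
        """True iff leaves a and b are each other's closest relatives."""
        if a == b:
            return False
        mrca = self._tree.mrca(taxon_labels=[a, b])
        children = mrca.child_nodes()
        labels = {
            c.taxon.label for c in children if c.is_leaf() and c.taxon
        }
        return {a, b} == labels and len(children) == 2

    def clade_leafsets(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node (monophyletic groups)."""
        out = []
        for node in self._tree.preorder_internal_node_iter():
            out.append(
                frozenset(lf.taxon.label for lf in node.leaf_iter())
            )
        return out

    def is_clade(self, species: set[str]) -> bool:
        return frozenset(species) in self.clade_leafsets()

    def patristic(self, a: str, b: str) -> float:
        """Patristic distance on the dated tree: twice the MRCA age."""
        return 2.0 * self.mrca_age(a, b)


def read_tree(path: str | Path, rel_tol: float = 1e-6) -> SpeciesTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return SpeciesTree(tree, rel_tol=rel_tol)


def demo_tree() -> SpeciesTree:
    """The packaged five-species demo tree (illustrative node ages).

    Only the BM-BD split (2.65 Mya) and the root (35 Mya) are anchored to
    published estimates; the remaining ages are interpolated placeholders.
    """
    with resources.files("httflow.data").joinpath("demo_tree.nwk").open() as fh:
        return SpeciesTree.from_newick(fh.read())


# ---------------------------------------------------------------------------
# Homology hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One BLAST-style homology hit (1-based inclusive query coordinates)."""

    query: str
    subject: str
    bitscore: float
    length: int
    pident: float
    qstart: int = 1
    qend: int = 1

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise FormatError(f"{self.query}: qstart > qend")
        if not 0.0 <= self.pident <= 100.0:
            raise FormatError(f"{self.query}: pident {self.pident} out of range")
        if self.bitscore < 0:
            raise FormatError(f"{self.query}: negative bit-score")


HIT_COLUMNS = ["qid", "sid", "bitscore", "length", "pident", "qstart", "qend"]


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a TSV hit table (columns: qid sid bitscore length pident qstart qend)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"hit table missing columns: {sorted(missing)}")
    return [
        HitRecord(
            query=str(r.qid), subject=str(r.sid), bitscore=float(r.bitscore),
            length=int(r.length), pident=float(r.pident),
            qstart=int(r.qstart), qend=int(r.qend),
        )
        for r in df.itertuples()
    ]


def write_hits(hits: list[HitRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            [h.query, h.subject, h.bitscore, h.length, h.pident, h.qstart, h.qend]
            for h in hits
        ],
        columns=HIT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Suitability grids
# ---------------------------------------------------------------------------


def read_suitability_grid(path: str | Path):
    """Read an ESRI ASCII grid or a headerless CSV matrix.

    ESRI ASCII is detected by a leading ``ncols`` header token. NODATA cells
    become masked and are excluded from all downstream sums.
    """
    from .eco_drivers import SuitabilityGrid  # local import: avoid cycle

    path = Path(path)
    first = path.open().readline().strip().lower()
    if first.startswith("ncols"):
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(x) for x in parts])
        values = np.array(rows)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise FormatError(f"{path.name}: grid shape does not match header")
        nodata = header.get("nodata_value")
        mask = (
            np.zeros(values.shape, bool)
            if nodata is None
            else values == nodata
        )
        return SuitabilityGrid(
            values=values, mask=mask, cellsize=header.get("cellsize", 1.0)
        )
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return SuitabilityGrid(
        values=values, mask=np.isnan(values), cellsize=1.0
    )


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Occurrence CSV with columns species, lon, lat (WGS84 decimal degrees)."""
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise FormatError(f"occurrence table missing columns: {sorted(missing)}")
    return df


def read_interaction_matrix(path: str | Path) -> pd.DataFrame:
    """Fly x flower interaction CSV; first column = fly species id."""
    return pd.read_csv(path, index_col=0)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def read_table3_fixture() -> pd.DataFrame:
    """Packaged superfamily x species-pair HTT incidence counts.

    Returns a DataFrame indexed by (order, superfamily) with the ten
    unordered species-pair columns; cells are non-negative event counts.
    """
    with resources.files("httflow.data").joinpath(
        "table3_htt_counts.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index(["order", "superfamily"])
    if list(df.columns) != FBD_PAIRS:
        raise FormatError("fixture columns do not match expected pair order")
    if (df.to_numpy() < 0).any():
        raise FormatError("fixture contains negative counts")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds, seed and resolution switches for a pipeline run."""

    min_bitscore: float = 160.0
    min_hit_length: int = 130
    redundancy_identity: float = 0.95
    cluster_identity: float = 0.90
    te_min_length: int = 600
    te_min_identity: float = 0.90
    alpha: float = 0.05
    similar_ds_rel_tol: float = 0.10
    calibration_age: float = 17.5
    alpha_resolution: str = "family"  # or "superfamily"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha_resolution not in {"family", "superfamily"}:
            raise ValueError("alpha_resolution must be family|superfamily")
        for name in ("redundancy_identity", "te_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def digest(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def log_header(self) -> str:
        return f"httflow run seed={self.seed} config={self.digest()}"
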