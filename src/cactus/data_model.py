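"""Domain types and I/O for clone genotypes, allele counts and cell clusterings.

The model consumes four pieces of data:

* a binary clone-genotype matrix ``omega`` (mutations x clones) produced by an
  upstream tumor-phylogeny tool,
* paired sparse count matrices ``alt`` / ``total`` (mutations x cells) of
  alternative-allele and total UMI counts at the mutated positions,
* an input clustering of the cells (e.g. by identical BCR heavy chain), and
* optionally a cell x cluster distance matrix.

Everything here is plain validation and plumbing; the probabilistic model
lives in :mod:`cactus.gibbs` and :mod:`cactus.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class CloneGenotypes:
    """Binary mutation-presence matrix of the tumor clones.

    ``omega[i, k] == 1`` iff mutation ``i`` is present in clone ``k``.  The
    first clone is conventionally the all-zero base (normal) clone, but this
    is not enforced.
    """

    mutation_ids: list[str]
    clone_ids: list[str]
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega)
        n, k = self.omega.shape
        if n != len(self.mutation_ids) or k != len(self.clone_ids):
            raise ValueError("omega shape does not match id lists")
        if n < 1 or k < 2:
            raise ValueError(f"need >=1 mutations and >=2 clones, got {n}x{k}")
        if not np.isin(self.omega, (0, 1)).all():
            raise FormatError("genotype matrix entries must be 0 or 1")
        if len(set(self.mutation_ids)) != n:
            raise ValueError("duplicate mutation ids in genotype matrix")
        self.omega = self.omega.astype(np.int8)

    @property
    def n_mutations(self) -> int:
        return self.omega.shape[0]

    @property
    def n_clones(self) -> int:
        return self.omega.shape[1]


@dataclass
class AlleleCounts:
    """Paired sparse alt/total UMI count matrices, mutations x cells.

    Entries with zero total coverage carry no information and contribute a
    likelihood factor of one; only covered entries are stored.
    """

    mutation_ids: list[str]
    cell_ids: list[str]
    alt: sp.csr_matrix
    total: sp.csr_matrix

    def __post_init__(self) -> None:
        self.alt = sp.csr_matrix(self.alt, dtype=np.int64)
        self.total = sp.csr_matrix(self.total, dtype=np.int64)
        if self.alt.shape != self.total.shape:
            raise ValueError(
                f"alt {self.alt.shape} and total {self.total.shape} shapes differ"
            )
        if self.alt.shape != (len(self.mutation_ids), len(self.cell_ids)):
            raise ValueError("count matrix shape does not match id lists")
        if (self.alt.data < 0).any() or (self.total.data < 0).any():
            raise ValueError("counts must be non-negative")
        # restrict alt to covered entries, then check alt <= total
        excess = (self.alt - self.total).tocoo()
        bad = excess.data > 0
        if bad.any():
            i = int(excess.row[bad][0])
            j = int(excess.col[bad][0])
            raise ValueError(
                f"alt count exceeds total at mutation index {i}, cell index {j}"
            )
        self.alt.eliminate_zeros()
        self.total.eliminate_zeros()

    @property
    def n_mutations(self) -> int:
        return self.total.shape[0]

    @property
    def n_cells(self) -> int:
        return self.total.shape[1]


@dataclass
class InputClustering:
    """Non-overlapping, exhaustive partition of cells into clusters."""

    cell_ids: list[str]
    cluster_ids: list[str]
    cluster_index: np.ndarray  # per cell, 0-based index into cluster_ids

    def __post_init__(self) -> None:
        self.cluster_index = np.asarray(self.cluster_index, dtype=np.int64)
        if self.cluster_index.shape != (len(self.cell_ids),):
            raise ValueError("cluster_index length must equal number of cells")
        q = len(self.cluster_ids)
        if self.cluster_index.min(initial=0) < 0 or (
            len(self.cell_ids) and self.cluster_index.max() >= q
        ):
            raise ValueError("cluster index out of range")
        sizes = np.bincount(self.cluster_index, minlength=q)
        if (sizes == 0).any():
            empty = [self.cluster_ids[i] for i in np.flatnonzero(sizes == 0)]
            raise ValueError(f"empty clusters: {empty}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_index, minlength=self.n_clusters)

    @property
    def is_multiplet(self) -> np.ndarray:
        """Boolean per cluster: True when the cluster has >= 2 cells."""
        return self.sizes >= 2

    def cluster_of(self, cell_id: str) -> str:
        return self.cluster_ids[self.cluster_index[self.cell_ids.index(cell_id)]]


@dataclass
class DistanceMatrix:
    """Cell x cluster distances (number of differing BCR mutations)."""

    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be 2-D (cells x clusters)")
        if not np.isfinite(self.G).all() or (self.G < 0).any():
            raise ValueError("distances must be finite and non-negative")

    def validate_against(self, clustering: InputClustering) -> None:
        own = self.G[np.arange(len(clustering.cell_ids)), clustering.cluster_index]
        if (own != 0).any():
            j = int(np.flatnonzero(own)[0])
            raise ValueError(
                f"distance of cell {clustering.cell_ids[j]} to its own cluster is "
                f"{own[j]}, expected 0"
            )


@dataclass
class Hyperparameters:
    """Beta-prior hyperparameters and the cluster-prior strength.

    Defaults place theta0 (allelic observation in a non-carrying cell) at a
    sequencing-error scale ~0.01, theta_i (carrying cell) near 0.46 reflecting
    allelic imbalance and dropout, and xi (genotype error rate) at prior mean
    0.1 with weak strength.
    """

    c: float = 2.0
    kappa: tuple[float, float] = (1.0, 9.0)
    v0: tuple[float, float] = (0.3, 29.7)
    v1: tuple[float, float] = (2.25, 2.65)

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("prior strength c must be >= 0")
        for name in ("kappa", "v0", "v1"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class JoinReport:
    """Before/after counts of the mutation and cell filters."""

    n_mutations_before: int
    n_mutations_after: int
    n_cells_before: int
    n_cells_after: int
    n_clusters_before: int
    n_clusters_after: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ClonalData:
    """Joined, filtered dataset the sampler operates on.

    Covered count entries are exposed as parallel coordinate arrays
    (``row``, ``col``, ``a``, ``d``) for vectorized likelihood evaluation.
    """

    genotypes: CloneGenotypes
    counts: AlleleCounts
    clustering: InputClustering
    distances: DistanceMatrix | None = None
    report: JoinReport | None = None
    # coordinate view of covered entries, filled in __post_init__
    row: np.ndarray = field(init=False)
    col: np.ndarray = field(init=False)
    a: np.ndarray = field(init=False)
    d: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.genotypes.mutation_ids != self.counts.mutation_ids:
            raise ValueError("genotype and count mutation axes differ")
        if self.counts.cell_ids != self.clustering.cell_ids:
            raise ValueError("count and clustering cell axes differ")
        coo = self.counts.total.tocoo()
        order = np.lexsort((coo.col, coo.row))
        self.row = coo.row[order].astype(np.int64)
        self.col = coo.col[order].astype(np.int64)
        self.d = coo.data[order]
        if self.row.size:
            alt = self.counts.alt.tocsr()
            self.a = np.asarray(alt[self.row, self.col]).ravel().astype(np.int64)
        else:
            self.a = np.zeros(0, dtype=np.int64)
        if self.distances is not None:
            if self.distances.G.shape != (
                self.clustering.n_cells,
                self.clustering.n_clusters,
            ):
                raise ValueError("distance matrix shape mismatch")
            self.distances.validate_against(self.clustering)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        """(N mutations, M cells, K clones, Q clusters)."""
        return (
            self.genotypes.n_mutations,
            self.clustering.n_cells,
            self.genotypes.n_clones,
            self.clustering.n_clusters,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def load_genotypes(path: str | Path) -> CloneGenotypes:
    """Read a clone-genotype TSV: header of clone ids, first column mutation ids."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"genotype file is missing or empty: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"genotype file has no data rows: {path}")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"non-binary entry in genotype matrix: {path}")
    return CloneGenotypes(
        mutation_ids=[str(m) for m in df.index],
        clone_ids=[str(c) for c in df.columns],
        omega=values,
    )


def write_genotypes(g: CloneGenotypes, path: str | Path) -> None:
    pd.DataFrame(g.omega, index=g.mutation_ids, columns=g.clone_ids).to_csv(
        path, sep="\t", index_label="mutation_id"
    )


def _read_matrix(path: Path) -> sp.csr_matrix:
    if path.suffix == ".mtx":
        return sp.csr_matrix(scipy.io.mmread(path))
    return sp.csr_matrix(
        pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=np.int64)
    )


def _read_ids(path: Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def load_counts(
    alt_path: str | Path,
    total_path: str | Path,
    mutations_path: str | Path,
    cells_path: str | Path,
) -> AlleleCounts:
    """Read alt/total matrices (MatrixMarket ``.mtx`` or dense TSV) with axis files."""
    alt = _read_matrix(Path(alt_path))
    total = _read_matrix(Path(total_path))
    return AlleleCounts(
        mutation_ids=_read_ids(Path(mutations_path)),
        cell_ids=_read_ids(Path(cells_path)),
        alt=alt,
        total=total,
    )


def write_counts(counts: AlleleCounts, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "alt.mtx", counts.alt.tocoo(), field="integer")
    scipy.io.mmwrite(outdir / "total.mtx", counts.total.tocoo(), field="integer")
    (outdir / "mutations.txt").write_text("\n".join(counts.mutation_ids) + "\n")
    (outdir / "barcodes.txt").write_text("\n".join(counts.cell_ids) + "\n")


def load_clustering(path: str | Path) -> InputClustering:
    """Read ``clusters.tsv``: barcode TAB cluster id, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "cluster"], dtype=str)
    cluster_ids = list(dict.fromkeys(df["cluster"]))
    lookup = {c: i for i, c in enumerate(cluster_ids)}
    return InputClustering(
        cell_ids=list(df["cell"]),
        cluster_ids=cluster_ids,
        cluster_index=np.array([lookup[c] for c in df["cluster"]]),
    )


def write_clustering(clustering: InputClustering, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cell, qi in zip(clustering.cell_ids, clustering.cluster_index):
            fh.write(f"{cell}\t{clustering.cluster_ids[qi]}\n")


def load_distances(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix(pd.read_csv(path, sep="\t", index_col=0).to_numpy())


def write_distances(
    dist: DistanceMatrix, clustering: InputClustering, path: str | Path
) -> None:
    pd.DataFrame(
        dist.G, index=clustering.cell_ids, columns=clustering.cluster_ids
    ).to_csv(path, sep="\t", index_label="cell")


# ---------------------------------------------------------------------------
# joining / filtering
# ---------------------------------------------------------------------------


def join_axes(
    genotypes: CloneGenotypes,
    counts: AlleleCounts,
    clustering: InputClustering,
    distances: DistanceMatrix | None = None,
    require_alt_read: bool = True,
) -> ClonalData:
    """Intersect axes and apply the mutation / cell filters.

    A mutation is retained when it appears in both the genotype matrix and the
    count matrices and has at least one variant read in at least one cell.
    A cell is retained when it has at least one variant read among retained
    mutations (``require_alt_read=True``, default) or at least one covered
    read (``require_alt_read=False``).  Clusters emptied by the cell filter
    are dropped and cluster indices are re-densified.
    """
    common = [m for m in genotypes.mutation_ids if m in set(counts.mutation_ids)]
    if not common:
        raise ValueError("no common mutations between genotypes and counts")
    g_idx = [genotypes.mutation_ids.index(m) for m in common]
    c_idx = [counts.mutation_ids.index(m) for m in common]
    if counts.cell_ids != clustering.cell_ids:
        keep_cells = [j for j, c in enumerate(counts.cell_ids) if c in set(clustering.cell_ids)]
        if not keep_cells:
            raise ValueError("no common cells between counts and clustering")
    else:
        keep_cells = list(range(counts.n_cells))

    alt = counts.alt[c_idx][:, keep_cells]
    total = counts.total[c_idx][:, keep_cells]
    evidence = alt if require_alt_read else total

    mut_keep = np.flatnonzero(np.asarray((evidence > 0).sum(axis=1)).ravel() > 0)
    alt, total = alt[mut_keep], total[mut_keep]
    evidence = alt if require_alt_read else total
    cell_keep = np.flatnonzero(np.asarray((evidence > 0).sum(axis=0)).ravel() > 0)

    cell_ids = [counts.cell_ids[keep_cells[j]] for j in cell_keep]
    mutation_ids = [common[i] for i in mut_keep]

    # restrict the clustering to retained cells, dropping emptied clusters
    pos = {c: i for i, c in enumerate(clustering.cell_ids)}
    old_q = clustering.cluster_index[[pos[c] for c in cell_ids]]
    kept_q = sorted(set(old_q.tolist()))
    remap = {q: i for i, q in enumerate(kept_q)}
    new_clustering = InputClustering(
        cell_ids=cell_ids,
        cluster_ids=[clustering.cluster_ids[q] for q in kept_q],
        cluster_index=np.array([remap[q] for q in old_q], dtype=np.int64),
    )

    new_distances = None
    if distances is not None:
        rows = [pos[c] for c in cell_ids]
        new_distances = DistanceMatrix(distances.G[np.ix_(rows, kept_q)])

    report = JoinReport(
        n_mutations_before=genotypes.n_mutations,
        n_mutations_after=len(mutation_ids),
        n_cells_before=counts.n_cells,
        n_cells_after=len(cell_ids),
        n_clusters_before=clustering.n_clusters,
        n_clusters_after=new_clustering.n_clusters,
    )
    return ClonalData(
        genotypes=CloneGenotypes(
            mutation_ids=mutation_ids,
            clone_ids=list(genotypes.clone_ids),
            omega=genotypes.omega[g_idx][mut_keep],
        ),
        counts=AlleleCounts(
            mutation_ids=mutation_ids,
            cell_ids=cell_ids,
            alt=alt[:, cell_keep],
            total=total[:, cell_keep],
        ),
        clustering=new_clustering,
        distances=new_distances,
        report=report,
    )
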