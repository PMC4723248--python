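"""Two-color expression microarray analysis with an empirical null.

Gene-level log2 expression ratios (each array compared against the
unstressed wild-type reference) are analysed as follows:

* a self-self ("wt x wt") hybridization, in which the reference is
  compared against itself, defines the technical-noise null; the change
  threshold is k standard deviations of that null (k = 3 by default,
  giving +/-0.65 log2 units, a 1.57-fold change, for a null SD of 0.22),
* replicate arrays are averaged per (strain, timepoint) in log2 space,
* mutant-effect ratios subtract the wild-type average from each mutant
  average at the matched timepoint,
* genes beyond the threshold are collected per column, with telomere
  proximity annotated from the genome coordinates,
* contiguous runs of genes uniformly elevated in one strain across all of
  its arrays are flagged as aneuploid and removed,
* significant genes are clustered by average-linkage agglomeration under
  the uncentered-correlation similarity, written as TreeView-compatible
  CDT/GTR files.

Coordinates are 1-based inclusive internally; BED output converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_K = 3.0
DEFAULT_TELOMERE_DISTANCE_BP = 25_000
DEFAULT_MIN_RUN = 5


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ExpressionSet:
    """Genes x arrays log2 ratios with array metadata and gene coordinates.

    ``values``: DataFrame indexed by gene id, one column per array id.
    ``arrays``: DataFrame indexed by array id with columns ``strain``,
    ``timepoint`` (minutes), ``replicate``.
    ``genes``: DataFrame indexed by gene id with columns ``chrom``,
    ``start``, ``end`` (1-based inclusive), in genome order.
    ``chrom_lengths``: chromosome id -> length in bp.
    """

    values: pd.DataFrame
    arrays: pd.DataFrame
    genes: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.arrays.index):
            raise ValueError("array columns and array metadata rows must match")
        if list(self.values.index) != list(self.genes.index):
            raise ValueError("gene rows and gene annotation rows must match")
        for col in ("strain", "timepoint", "replicate"):
            if col not in self.arrays.columns or self.arrays[col].isna().any():
                raise ValueError(f"incomplete array metadata column {col!r}")
        for col in ("chrom", "start", "end"):
            if col not in self.genes.columns:
                raise ValueError(f"gene annotation missing column {col!r}")
        for chrom, sub in self.genes.groupby("chrom", sort=False):
            length = self.chrom_lengths.get(chrom)
            if length is not None and int(sub["end"].max()) > length:
                raise ValueError(f"gene coordinates exceed length of {chrom}")
            if (sub["start"] < 1).any() or (sub["end"] < sub["start"]).any():
                raise ValueError(f"invalid gene coordinates on {chrom}")

    def arrays_for(
        self, strain: str | None = None, timepoint: int | None = None
    ) -> list[str]:
        meta = self.arrays
        sel = pd.Series(True, index=meta.index)
        if strain is not None:
            sel &= meta["strain"] == strain
        if timepoint is not None:
            sel &= meta["timepoint"] == timepoint
        return list(meta.index[sel])

    def drop_genes(self, gene_ids) -> "ExpressionSet":
        keep = ~self.values.index.isin(set(gene_ids))
        return replace(
            self, values=self.values.loc[keep], genes=self.genes.loc[keep]
        )


@dataclass(frozen=True)
class ThresholdResult:
    """Empirical-null change threshold derived from a self-self array."""

    null_sd: float
    k: float
    null_mean: float
    n_used: int
    n_excluded: int = 0

    @property
    def log2_threshold(self) -> float:
        return self.k * self.null_sd

    @property
    def fold_threshold(self) -> float:
        return float(2.0 ** self.log2_threshold)


@dataclass(frozen=True)
class AveragedMatrix:
    """Replicate-averaged log2 ratios per gene x (strain, timepoint).

    ``values`` has MultiIndex columns (strain, timepoint); ``n`` holds the
    number of finite replicate values behind each cell (0 marks an
    undefined cell, which is NaN in ``values``).
    """

    values: pd.DataFrame
    n: pd.DataFrame


@dataclass(frozen=True)
class GenomicRegion:
    """A contiguous run of genes (genome order) on one chromosome."""

    chrom: str
    first_gene: str
    last_gene: str
    gene_ids: tuple[str, ...]
    start_bp: int
    end_bp: int
    mean_elevation: float

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ---------------------------------------------------------------------------
# empirical null and thresholding


def derive_threshold(
    self_self_ratios, k: float = DEFAULT_K
) -> ThresholdResult:
    """Derive the significance threshold from self-self log2 ratios.

    The threshold is k sample standard deviations (n-1 denominator) of the
    null distribution, centered at 0; the null mean is reported for QC
    only.  Non-finite values are excluded (counted); fewer than 100 finite
    values is an error — a null that small is not meaningful.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    arr = np.asarray(self_self_ratios, dtype=float).ravel()
    finite = np.isfinite(arr)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.warning("derive_threshold: excluded %d non-finite ratios", n_excluded)
    arr = arr[finite]
    if arr.size < 100:
        raise ValueError(
            f"need >=100 finite self-self ratios to estimate the null, got {arr.size}"
        )
    return ThresholdResult(
        null_sd=float(np.std(arr, ddof=1)),
        k=float(k),
        null_mean=float(arr.mean()),
        n_used=int(arr.size),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# averaging and mutant effects


def average_replicates(expr: ExpressionSet) -> AveragedMatrix:
    """Average log2 ratios over replicates per (strain, timepoint).

    Missing (NaN) values are excluded pairwise; the per-cell count of
    usable replicates is recorded.  A cell with zero usable replicates is
    NaN with n = 0.
    """
    cols = pd.MultiIndex.from_frame(
        expr.arrays[["strain", "timepoint"]].reset_index(drop=True)
    )
    data = expr.values.copy()
    data.columns = cols
    grouped = data.T.groupby(level=["strain", "timepoint"], sort=True)
    values = grouped.mean().T
    counts = grouped.count().T.astype(int)
    n_undefined = int((counts == 0).to_numpy().sum())
    if n_undefined:
        logger.warning("average_replicates: %d undefined cells (no replicates)", n_undefined)
    return AveragedMatrix(values=values, n=counts)


def mutant_effect(avg: AveragedMatrix, wild_type: str) -> pd.DataFrame:
    """Mutant-effect ratios: mutant minus wild type, in log2 space.

    For each mutant strain m and timepoint t, cell (g, m, t) is
    avg(g, m, t) - avg(g, wild_type, t).  Missing wild-type cells leave
    the affected mutant cells NaN (flagged via a logged warning).
    """
    strains = avg.values.columns.get_level_values("strain")
    if wild_type not in set(strains):
        raise ValueError(f"wild-type strain {wild_type!r} absent from averages")
    wt = avg.values[wild_type]
    out = {}
    for strain in sorted(set(strains) - {wild_type}):
        sub = avg.values[strain]
        for tp in sub.columns:
            if tp not in wt.columns:
                logger.warning(
                    "mutant_effect: no wild-type average at %s min; (%s, %s) undefined",
                    tp, strain, tp,
                )
                out[(strain, tp)] = pd.Series(np.nan, index=sub.index)
            else:
                out[(strain, tp)] = sub[tp] - wt[tp]
    effects = pd.DataFrame(out)
    effects.columns = pd.MultiIndex.from_tuples(
        effects.columns, names=["strain", "timepoint"]
    )
    return effects


# ---------------------------------------------------------------------------
# significance calls and telomere proximity


def call_significant(
    values: pd.DataFrame, log2_threshold: float, direction: str = "both"
) -> dict:
    """Genes beyond the log2 threshold, per column; boundary inclusive.

    ``direction``: "up" keeps value >= threshold, "down" keeps
    value <= -threshold, "both" keeps |value| >= threshold.  Returns a
    mapping column -> set of gene ids (NaN cells never qualify).
    """
    if log2_threshold < 0:
        raise ValueError("log2_threshold must be >= 0")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    out = {}
    for col in values.columns:
        v = values[col]
        if direction == "up":
            mask = v >= log2_threshold
        elif direction == "down":
            mask = v <= -log2_threshold
        else:
            mask = v.abs() >= log2_threshold
        out[col] = set(values.index[mask.fillna(False)])
    return out


def telomere_proximity(
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int],
    max_distance_bp: int = DEFAULT_TELOMERE_DISTANCE_BP,
) -> pd.Series:
    """Flag genes within ``max_distance_bp`` of a chromosome end.

    Distance to the left telomere is start - 1; to the right telomere,
    chromosome length - end (1-based inclusive coordinates).
    """
    if max_distance_bp <= 0:
        raise ValueError("max_distance_bp must be positive")
    unknown = set(genes["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"genes on unknown chromosomes: {sorted(unknown)}")
    lengths = genes["chrom"].map(chrom_lengths)
    dist = np.minimum(genes["start"] - 1, lengths - genes["end"])
    return (dist <= max_distance_bp).rename("telomere_proximal")


# ---------------------------------------------------------------------------
# aneuploidy scan


def detect_aneuploid_region(
    expr: ExpressionSet,
    strain: str,
    elevation_cutoff: float,
    min_run: int = DEFAULT_MIN_RUN,
) -> tuple[list[GenomicRegion], ExpressionSet]:
    """Scan one strain for contiguous runs of uniformly elevated genes.

    A gene qualifies when its mean log2 ratio across all arrays of the
    strain exceeds ``elevation_cutoff`` AND the strain shows the gene
    elevated (replicate-mean above 0) at every timepoint — the
    copy-number signature is constitutive, not stress-responsive.
    Maximal runs of >= ``min_run`` consecutive qualifying
    genes in genome order on one chromosome are reported, and a copy of
    the expression set with the region genes removed is returned.
    """
    if min_run < 3:
        raise ValueError("min_run must be >= 3")
    array_ids = expr.arrays_for(strain=strain)
    if not array_ids:
        raise ValueError(f"no arrays for strain {strain!r}")

    order = expr.genes.sort_values(["chrom", "start"], kind="mergesort").index
    sub = expr.values.loc[order, array_ids]
    mean = sub.mean(axis=1)
    tps = expr.arrays.loc[array_ids, "timepoint"]
    elevated_every_tp = pd.Series(True, index=sub.index)
    for tp in sorted(set(tps)):
        cols = [a for a in array_ids if tps[a] == tp]
        elevated_every_tp &= sub[cols].mean(axis=1) > 0
    qualifies = (mean > elevation_cutoff) & elevated_every_tp

    regions: list[GenomicRegion] = []
    genes = expr.genes.loc[order]
    chroms = genes["chrom"].to_numpy()
    q = qualifies.to_numpy()
    i = 0
    while i < len(order):
        if not q[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(order) and q[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        if j - i + 1 >= min_run:
            ids = tuple(order[i : j + 1])
            regions.append(
                GenomicRegion(
                    chrom=str(chroms[i]),
                    first_gene=ids[0],
                    last_gene=ids[-1],
                    gene_ids=ids,
                    start_bp=int(genes["start"].iloc[i]),
                    end_bp=int(genes["end"].iloc[j]),
                    mean_elevation=float(mean.iloc[i : j + 1].mean()),
                )
            )
        i = j + 1

    masked_ids = [g for r in regions for g in r.gene_ids]
    if masked_ids:
        logger.info(
            "aneuploidy scan (%s): %d region(s), %d genes removed",
            strain, len(regions), len(masked_ids),
        )
    return regions, expr.drop_genes(masked_ids)


# ---------------------------------------------------------------------------
# similarity and clustering


def uncentered_correlation(x, y) -> float:
    """Cosine-like similarity Sum(x*y) / sqrt(Sum(x^2) * Sum(y^2)).

    Pearson correlation without mean-centering, evaluated over positions
    where both vectors are finite.  A zero-norm vector has no defined
    similarity and raises.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need >=2 jointly finite positions")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero-norm vector")
    return float((x * y).sum() / (nx * ny))


@dataclass(frozen=True)
class ClusterResult:
    """Agglomeration result: merge list plus leaf ordering.

    ``merges``: one row per merge as (left, right, height, size) where
    cluster ids 0..n-1 are the input rows, id n+i is the cluster created
    by merge i, and height is 1 - average inter-cluster similarity.
    ``leaf_order``: input row indices in dendrogram order.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    n_leaves: int


def hcluster_average(matrix, similarity=uncentered_correlation) -> ClusterResult:
    """Average-linkage agglomerative clustering on a similarity.

    At each step the pair of clusters with the highest average
    inter-cluster similarity merges; the average is maintained by the
    size-weighted Lance-Williams update.  Ties break deterministically on
    the lowest (left, right) cluster-id pair.  Merge heights are
    1 - similarity, so identical rows merge at height 0.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >=2 rows")
    n = X.shape[0]

    sim: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    bad: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = similarity(X[i], X[j])
            except ValueError:
                bad.append((i, j))
                continue
            sim[i][j] = sim[j][i] = s
    if bad:
        raise ValueError(f"similarity undefined for row pairs: {bad}")

    sizes = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                s = sim[a][b]
                if best is None or s > best[0]:
                    best = (s, a, b)
        s, a, b = best
        size = sizes[a] + sizes[b]
        merges.append((a, b, 1.0 - s, size))
        children[next_id] = (a, b)
        sizes[next_id] = size
        sim[next_id] = {}
        for c in active:
            if c in (a, b):
                continue
            v = (sizes[a] * sim[a][c] + sizes[b] * sim[b][c]) / size
            sim[next_id][c] = sim[c][next_id] = v
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return leaves(left) + leaves(right)

    return ClusterResult(merges=merges, leaf_order=leaves(next_id - 1), n_leaves=n)


def set_overlaps(gene_sets: dict) -> dict:
    """Pairwise (and, for 3 sets, Venn-region) intersection counts.

    With exactly two or three named sets the exclusive Venn-region
    cardinalities are included; with more than three sets only pairwise
    intersections are reported.
    """
    names = list(gene_sets)
    if len(names) < 2:
        raise ValueError("need >=2 gene sets")
    sets = {k: set(v) for k, v in gene_sets.items()}
    out: dict = {"sizes": {k: len(v) for k, v in sets.items()}, "pairwise": {}}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out["pairwise"][(a, b)] = len(sets[a] & sets[b])
    if len(names) == 2:
        a, b = names
        out["regions"] = {
            (a,): len(sets[a] - sets[b]),
            (b,): len(sets[b] - sets[a]),
            (a, b): len(sets[a] & sets[b]),
        }
    elif len(names) == 3:
        a, b, c = names
        abc = sets[a] & sets[b] & sets[c]
        out["triple"] = len(abc)
        out["regions"] = {
            (a,): len(sets[a] - sets[b] - sets[c]),
            (b,): len(sets[b] - sets[a] - sets[c]),
            (c,): len(sets[c] - sets[a] - sets[b]),
            (a, b): len((sets[a] & sets[b]) - sets[c]),
            (a, c): len((sets[a] & sets[c]) - sets[b]),
            (b, c): len((sets[b] & sets[c]) - sets[a]),
            (a, b, c): len(abc),
        }
    return out


# ---------------------------------------------------------------------------
# file formats


def write_expression_tsv(expr: ExpressionSet, path) -> None:
    """TSV with gene coordinates then one column per array.

    Array columns are named ``strain_timepoint_replicate``; chromosome
    lengths are kept on a leading ``#chrom_lengths`` comment line.
    """
    with open(path, "w") as fh:
        if expr.chrom_lengths:
            pairs = " ".join(f"{c}:{l}" for c, l in expr.chrom_lengths.items())
            fh.write(f"#chrom_lengths {pairs}\n")
        table = expr.genes[["chrom", "start", "end"]].join(expr.values)
        table.index.name = "gene_id"
        table.to_csv(fh, sep="\t")


def read_expression_tsv(path) -> ExpressionSet:
    """Inverse of :func:`write_expression_tsv`."""
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#chrom_lengths"):
            for pair in first.split()[1:]:
                c, l = pair.split(":")
                chrom_lengths[c] = int(l)
        else:
            fh.seek(0)
        table = pd.read_csv(fh, sep="\t", index_col="gene_id")
    genes = table[["chrom", "start", "end"]]
    values = table.drop(columns=["chrom", "start", "end"]).astype(float)
    meta = []
    for col in values.columns:
        strain, tp, rep = col.rsplit("_", 2)
        meta.append({"array_id": col, "strain": strain, "timepoint": int(tp), "replicate": rep})
    arrays = pd.DataFrame(meta).set_index("array_id")
    if not chrom_lengths:
        chrom_lengths = {
            c: int(sub["end"].max()) for c, sub in genes.groupby("chrom")
        }
    return ExpressionSet(values=values, arrays=arrays, genes=genes, chrom_lengths=chrom_lengths)


def write_bed(regions: list[GenomicRegion], path) -> None:
    """Regions as BED (0-based half-open; score = mean elevation)."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.first_gene}-{r.last_gene}"
            fh.write(
                f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\t{r.mean_elevation:.4f}\n"
            )


def write_cdt_gtr(
    matrix: pd.DataFrame, result: ClusterResult, cdt_path, gtr_path
) -> None:
    """TreeView-compatible clustered data table and gene-tree files.

    The GTR lists merges as NODE/GENE identifiers with the similarity
    (1 - height) at each join; the CDT holds the matrix reordered by the
    dendrogram leaf order.
    """
    n = result.n_leaves
    if len(matrix) != n:
        raise ValueError("matrix row count does not match clustering")

    def node_name(idx: int) -> str:
        return f"GENE{idx}X" if idx < n else f"NODE{idx - n + 1}X"

    with open(gtr_path, "w") as fh:
        for k, (a, b, height, _size) in enumerate(result.merges):
            fh.write(
                f"NODE{k + 1}X\t{node_name(a)}\t{node_name(b)}\t{1.0 - height:.6f}\n"
            )

    ordered = matrix.iloc[result.leaf_order]
    with open(cdt_path, "w") as fh:
        cols = "\t".join(str(c) for c in matrix.columns)
        fh.write(f"GID\tUNIQID\tNAME\tGWEIGHT\t{cols}\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1"] * matrix.shape[1]) + "\n")
        for row_pos, (gene, row) in zip(result.leaf_order, ordered.iterrows()):
            vals = "\t".join("" if pd.isna(v) else f"{v:.6f}" for v in row)
            fh.write(f"GENE{row_pos}X\t{gene}\t{gene}\t1\t{vals}\n")
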