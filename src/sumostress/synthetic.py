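"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis stages
assume, so each stage is testable offline against a planted truth:

* spectral counts — per-protein summed counts are Poisson draws (optional
  negative-binomial overdispersion) around a baseline mean at 0 minutes
  and baseline x fold at 15 minutes for planted stress-enriched proteins;
  sums are split uniformly across peptides, and a configurable fraction
  of decoy records falls below the identification-probability cutoff,
* expression arrays — per-gene log2 ratios are planted effect + optional
  aneuploid-segment shift + Gaussian replicate noise, on a deterministic
  synthetic genome (3 chromosomes, evenly spaced genes, 1-based inclusive
  coordinates),
* image fields — cells are non-overlapping ellipses with interior
  nuclear ellipses; intensity is a cytoplasmic baseline, a nuclear
  enrichment, Gaussian spots in inclusion-positive cells, and additive
  Gaussian noise clipped at zero.

All generators are pure functions of (truth, seed): identical inputs
yield identical outputs.  Ground truth is returned alongside every
dataset; downstream recovery tests never read hidden state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import ExpressionSet
from .imaging import ImageField
from .proteomics import (
    DEFAULT_MIN_PROBABILITY,
    PEPTIDE_COLUMNS,
    ProteinCountMatrix,
    TIMEPOINT_BASELINE,
    TIMEPOINT_STRESS,
)

# ---------------------------------------------------------------------------
# spectral counts


@dataclass(frozen=True)
class SpectralTruth:
    """Design of a synthetic spectral-count experiment.

    ``planted_fold`` may be a single positive real applied to every
    planted protein or a mapping protein id -> fold; folds must be >= 1.
    ``overdispersion`` switches the count model from Poisson to a
    negative binomial with that dispersion (variance mu + mu^2/size).
    """

    n_proteins: int = 500
    planted_proteins: tuple[str, ...] = ()
    planted_fold: float | dict = 3.0
    baseline_mean: float = 20.0
    n_replicates: int = 3
    seed: int = 0
    peptides_per_protein: int = 3
    low_prob_fraction: float = 0.1
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per timepoint")
        if not 0 <= self.low_prob_fraction < 1:
            raise ValueError("low_prob_fraction must lie in [0, 1)")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >=1")
        for p in self.planted_proteins:
            if self.fold_for(p) < 1:
                raise ValueError("planted folds must be >= 1")

    def fold_for(self, protein_id: str) -> float:
        if isinstance(self.planted_fold, dict):
            return float(self.planted_fold[protein_id])
        return float(self.planted_fold)


def protein_ids(n: int) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(n)]


def gen_spectral_counts(
    truth: SpectralTruth, min_probability: float = DEFAULT_MIN_PROBABILITY
) -> tuple[pd.DataFrame, ProteinCountMatrix]:
    """Generate a peptide identification table plus its ground truth.

    Records whose probability is >= ``min_probability`` carry exactly the
    planted per-protein summed counts; an additional ``low_prob_fraction``
    of decoy records falls below the cutoff (these must be removed by the
    probability filter to recover the truth).  Returns (peptide table,
    ground-truth ProteinCountMatrix of summed counts).
    """
    rng = np.random.default_rng(truth.seed)
    prots = protein_ids(truth.n_proteins)
    unknown = set(truth.planted_proteins) - set(prots)
    if unknown:
        raise ValueError(f"planted proteins outside the roster: {sorted(unknown)}")

    timepoints = (TIMEPOINT_BASELINE, TIMEPOINT_STRESS)
    sample_meta = pd.DataFrame(
        [
            {"sample_id": f"{tp}min_r{r + 1}", "timepoint": tp, "replicate": r + 1}
            for tp in timepoints
            for r in range(truth.n_replicates)
        ]
    ).set_index("sample_id")

    folds = np.ones(truth.n_proteins)
    for p in truth.planted_proteins:
        folds[prots.index(p)] = truth.fold_for(p)
    means = np.empty((truth.n_proteins, len(sample_meta)))
    for j, sid in enumerate(sample_meta.index):
        tp = sample_meta.loc[sid, "timepoint"]
        means[:, j] = truth.baseline_mean * (folds if tp == TIMEPOINT_STRESS else 1.0)

    if truth.overdispersion is None:
        counts = rng.poisson(means)
    else:
        size = truth.overdispersion
        counts = rng.negative_binomial(size, size / (size + means))

    matrix = ProteinCountMatrix(
        counts=pd.DataFrame(
            counts.astype(np.int64), index=pd.Index(prots, name="protein_id"),
            columns=sample_meta.index,
        ),
        samples=sample_meta,
    )

    # split each protein sum uniformly across its peptides
    k = truth.peptides_per_protein
    if k == 1:
        pi, sj = np.nonzero(counts)
        real = pd.DataFrame(
            {
                "protein_id": np.asarray(prots, dtype=object)[pi],
                "sample_id": sample_meta.index.to_numpy()[sj],
                "spectral_count": counts[pi, sj].astype(int),
            }
        )
        real["peptide"] = real["protein_id"] + "_pep1"
    else:
        rows = []
        for i, pid in enumerate(prots):
            for j, sid in enumerate(sample_meta.index):
                total = int(counts[i, j])
                if total == 0:
                    continue
                split = rng.multinomial(total, np.full(k, 1.0 / k))
                for pep_idx, c in enumerate(split):
                    if c == 0:
                        continue
                    rows.append((pid, f"{pid}_pep{pep_idx + 1}", sid, int(c)))
        real = pd.DataFrame(
            rows, columns=["protein_id", "peptide", "sample_id", "spectral_count"]
        )
    real["probability"] = rng.uniform(min_probability, 1.0, size=len(real))

    # decoy records below the probability cutoff
    if truth.low_prob_fraction > 0 and min_probability > 0:
        n_decoy = int(round(len(real) * truth.low_prob_fraction / (1 - truth.low_prob_fraction)))
        decoys = pd.DataFrame(
            {
                "protein_id": rng.choice(prots, size=n_decoy),
                "sample_id": rng.choice(sample_meta.index.to_numpy(), size=n_decoy),
                "spectral_count": rng.poisson(2.0, size=n_decoy) + 1,
                "probability": rng.uniform(0.0, min_probability * (1 - 1e-9), size=n_decoy),
            }
        )
        decoys["peptide"] = [
            f"{p}_decoy{i + 1}" for i, p in enumerate(decoys["protein_id"])
        ]
        table = pd.concat([real, decoys], ignore_index=True)
    else:
        table = real

    table = table.merge(
        sample_meta.reset_index(), on="sample_id", how="left"
    )[list(PEPTIDE_COLUMNS)]
    return table, matrix


# ---------------------------------------------------------------------------
# expression arrays


@dataclass(frozen=True)
class AneuploidSegment:
    """A contiguous genome-order gene segment with a copy-number shift.

    ``first_index``/``last_index`` are 0-based inclusive positions in the
    genome-ordered gene list; the segment must stay on ``chrom``.  The
    shift applies to every array of ``strain`` (or to one ``replicate``
    of it when given), at all timepoints — emulating a strain isolate
    that carries an extra chromosome segment.
    """

    chrom: str
    first_index: int
    last_index: int
    shift: float
    strain: str
    replicate: str | int | None = None

    def __post_init__(self) -> None:
        if self.last_index < self.first_index:
            raise ValueError("aneuploid segment indices must be ordered")


@dataclass(frozen=True)
class ArrayTruth:
    """Design of a synthetic expression-array experiment.

    ``planted_effects`` maps gene id -> {(strain, timepoint): log2 shift}.
    """

    n_genes: int = 600
    replicate_sd: float = 0.22
    planted_effects: dict = field(default_factory=dict)
    aneuploid_segment: AneuploidSegment | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be positive")
        if self.n_genes < 2:
            raise ValueError("need >=2 genes")


#: The synthetic genome: 3 chromosomes, evenly spaced genes of 1.5 kb with
#: 0.5 kb spacers, 1-based inclusive coordinates.
_GENE_SPACING = 2000
_GENE_LENGTH = 1500


def synthetic_annotation(n_genes: int) -> tuple[pd.DataFrame, dict[str, int]]:
    """Deterministic gene annotation: ids, coordinates, chromosome lengths."""
    n1 = n_genes // 4
    n2 = n_genes // 3
    counts = {"chrI": n1, "chrII": n2, "chrIII": n_genes - n1 - n2}
    rows = []
    i = 0
    for chrom, n in counts.items():
        for g in range(n):
            start = g * _GENE_SPACING + 501
            rows.append(
                {
                    "gene_id": f"G{i + 1:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + _GENE_LENGTH - 1,
                }
            )
            i += 1
    genes = pd.DataFrame(rows).set_index("gene_id")
    lengths = {c: n * _GENE_SPACING + 500 for c, n in counts.items() if n > 0}
    return genes, lengths


def gen_array_experiment(
    truth: ArrayTruth,
    strains: tuple[str, ...] = ("wt", "tup1KR", "cyc8KR"),
    timepoints: tuple[int, ...] = (0, 30, 60),
    n_replicates: int = 2,
    wild_type: str = "wt",
) -> tuple[ExpressionSet, ArrayTruth]:
    """Simulate gene-level log2 ratios for a strain x timepoint design.

    Each array's per-gene value is planted effect (0 for unplanted genes)
    + aneuploid shift (for genes in the segment on flagged arrays) +
    Gaussian noise with SD ``replicate_sd``.
    """
    if n_replicates < 2:
        raise ValueError("need >=2 replicates")
    if wild_type not in strains:
        raise ValueError(f"strains must include the wild-type label {wild_type!r}")
    genes, chrom_lengths = synthetic_annotation(truth.n_genes)
    gene_index = genes.index

    for g, cells in truth.planted_effects.items():
        if g not in gene_index:
            raise ValueError(f"planted effect on unknown gene {g!r}")
        for strain, tp in cells:
            if strain not in strains or tp not in timepoints:
                raise ValueError(
                    f"planted effect at unknown cell ({strain!r}, {tp!r})"
                )

    seg = truth.aneuploid_segment
    if seg is not None:
        if seg.strain not in strains:
            raise ValueError(f"aneuploid strain {seg.strain!r} not in design")
        seg_chroms = set(genes["chrom"].iloc[seg.first_index : seg.last_index + 1])
        if seg_chroms != {seg.chrom}:
            raise ValueError("aneuploid segment must be contiguous on one chromosome")

    meta = pd.DataFrame(
        [
            {
                "array_id": f"{s}_{tp}_{r + 1}",
                "strain": s,
                "timepoint": tp,
                "replicate": r + 1,
            }
            for s in strains
            for tp in timepoints
            for r in range(n_replicates)
        ]
    ).set_index("array_id")

    rng = np.random.default_rng(truth.seed)
    values = rng.normal(0.0, truth.replicate_sd, size=(truth.n_genes, len(meta)))
    for g, cells in truth.planted_effects.items():
        gi = gene_index.get_loc(g)
        for (strain, tp), shift in cells.items():
            cols = (meta["strain"] == strain) & (meta["timepoint"] == tp)
            values[gi, cols.to_numpy()] += shift
    if seg is not None:
        flagged = meta["strain"] == seg.strain
        if seg.replicate is not None:
            flagged &= meta["replicate"] == seg.replicate
        values[seg.first_index : seg.last_index + 1, flagged.to_numpy()] += seg.shift

    expr = ExpressionSet(
        values=pd.DataFrame(values, index=gene_index, columns=meta.index),
        arrays=meta,
        genes=genes,
        chrom_lengths=chrom_lengths,
    )
    return expr, truth


def gen_self_self(n_genes: int, sd: float = 0.22, seed: int = 0) -> np.ndarray:
    """Self-self (wt x wt) hybridization null: i.i.d. Gaussian(0, sd)."""
    if n_genes < 2:
        raise ValueError("need >=2 genes")
    if sd <= 0:
        raise ValueError("sd must be positive")
    return np.random.default_rng(seed).normal(0.0, sd, size=n_genes)


# ---------------------------------------------------------------------------
# image fields


@dataclass(frozen=True)
class FieldTruth:
    """Design of one synthetic fluorescence field.

    ``nuclear_enrichment`` is the ratio of nuclear to cytoplasmic mean
    intensity; ``channel_overlap`` is the probability that a planted spot
    also appears in channel 2 when ``n_channels`` is 2.
    """

    n_cells: int = 40
    inclusion_fraction: float = 0.5
    spots_per_positive_cell: int = 1
    spot_amplitude: float = 150.0
    spot_sigma: float = 2.0
    nuclear_enrichment: float = 2.0
    noise_sd: float = 5.0
    seed: int = 0
    n_channels: int = 1
    channel_overlap: float = 1.0
    baseline: float = 100.0
    background: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.inclusion_fraction <= 1:
            raise ValueError("inclusion_fraction must lie in [0, 1]")
        if self.spots_per_positive_cell < 1:
            raise ValueError("spots_per_positive_cell must be >=1")
        if self.spot_amplitude <= 0 or self.spot_sigma <= 0:
            raise ValueError("spot amplitude and sigma must be positive")
        if self.nuclear_enrichment < 1:
            raise ValueError("nuclear_enrichment must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")
        if not 0 <= self.channel_overlap <= 1:
            raise ValueError("channel_overlap must lie in [0, 1]")


_CELL_RADIUS_RANGE = (7.0, 10.0)
_NUCLEUS_SCALE = 0.45


def _place_cells(rng, n_cells, shape):
    """Non-overlapping ellipse placement; explicit failure, never overlap."""
    r_max = _CELL_RADIUS_RANGE[1]
    margin = r_max + 2
    if shape[0] < 2 * margin + 1 or shape[1] < 2 * margin + 1:
        raise ValueError("field shape too small for any cell")
    placed = []  # (cy, cx, a, b, theta)
    attempts = 0
    budget = 500 * n_cells
    while len(placed) < n_cells:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in {shape} "
                f"after {budget} attempts"
            )
        attempts += 1
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        a = rng.uniform(*_CELL_RADIUS_RANGE)
        b = rng.uniform(*_CELL_RADIUS_RANGE)
        theta = rng.uniform(0, np.pi)
        r = max(a, b)
        ok = all(
            np.hypot(cy - py, cx - px) > r + max(pa, pb) + 1.0
            for py, px, pa, pb, _ in placed
        )
        if ok:
            placed.append((cy, cx, a, b, theta))
    return placed


def _paint_ellipse(mask, label, cy, cx, a, b, theta):
    r = int(np.ceil(max(a, b))) + 1
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0, x1 = int(cx) - r, int(cx) + r + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[y0:y1, x0:x1][inside] = label


def gen_image_field(
    truth: FieldTruth,
    shape: tuple[int, int] = (256, 256),
    share_noise: bool = False,
) -> ImageField:
    """Render one synthetic field with labeled masks and ground truth.

    Inclusion-positive cells are Bernoulli(``inclusion_fraction``) draws;
    each receives ``spots_per_positive_cell`` Gaussian spots whose centers
    lie inside the cell mask (verified).  With two channels, each spot
    appears in channel 2 with probability ``channel_overlap``; noise is
    drawn per channel unless ``share_noise``.
    """
    rng = np.random.default_rng(truth.seed)
    cells = _place_cells(rng, truth.n_cells, shape)

    cell_mask = np.zeros(shape, dtype=np.int32)
    nuclear_mask = np.zeros(shape, dtype=np.int32)
    for lab, (cy, cx, a, b, theta) in enumerate(cells, start=1):
        _paint_ellipse(cell_mask, lab, cy, cx, a, b, theta)
        _paint_ellipse(
            nuclear_mask, lab, cy, cx,
            max(a * _NUCLEUS_SCALE, 2.0), max(b * _NUCLEUS_SCALE, 2.0), theta,
        )
    nuclear_mask[cell_mask == 0] = 0  # guard discretization edges

    positive = rng.random(truth.n_cells) < truth.inclusion_fraction
    spots = []
    for lab, (cy, cx, a, b, theta) in enumerate(cells, start=1):
        if not positive[lab - 1]:
            continue
        for _ in range(truth.spots_per_positive_cell):
            for _try in range(100):
                rad = 0.7 * np.sqrt(rng.random())
                phi = rng.uniform(0, 2 * np.pi)
                u, v = a * rad * np.cos(phi), b * rad * np.sin(phi)
                sy = cy + u * np.cos(theta) - v * np.sin(theta)
                sx = cx + u * np.sin(theta) + v * np.cos(theta)
                if cell_mask[int(round(sy)), int(round(sx))] == lab:
                    break
            else:
                raise RuntimeError("could not place a spot inside its cell mask")
            in_ch2 = truth.n_channels == 2 and (
                truth.channel_overlap >= 1.0 or rng.random() < truth.channel_overlap
            )
            spots.append(
                {"label": lab, "row": sy, "col": sx, "channels": [0, 1] if in_ch2 else [0]}
            )

    base = np.full(shape, truth.background, dtype=float)
    base[cell_mask > 0] = truth.baseline
    base[nuclear_mask > 0] = truth.baseline * truth.nuclear_enrichment

    def render(channel_idx):
        img = base.copy()
        s = truth.spot_sigma
        r = int(np.ceil(4 * s))
        for spot in spots:
            if channel_idx not in spot["channels"]:
                continue
            cy, cx = spot["row"], spot["col"]
            y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, shape[0])
            x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, shape[1])
            yy, xx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += truth.spot_amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)
            )
        return img

    channels = [render(i) for i in range(truth.n_channels)]
    if truth.noise_sd > 0:
        if share_noise:
            noise = rng.normal(0.0, truth.noise_sd, size=shape)
            channels = [np.clip(c + noise, 0, None) for c in channels]
        else:
            channels = [
                np.clip(c + rng.normal(0.0, truth.noise_sd, size=shape), 0, None)
                for c in channels
            ]
    else:
        channels = [np.clip(c, 0, None) for c in channels]

    return ImageField(
        channels=channels,
        cell_mask=cell_mask,
        nuclear_mask=nuclear_mask,
        metadata={"n_cells": truth.n_cells, "seed": truth.seed},
        truth={
            "positive_labels": [int(l + 1) for l in np.flatnonzero(positive)],
            "spots": spots,
            "inclusion_fraction": truth.inclusion_fraction,
            "params": dataclasses.asdict(truth),
        },
    )


def gen_timecourse_fields(
    trajectory: dict,
    fields_per_timepoint: int,
    template: FieldTruth,
    shape: tuple[int, int] = (256, 256),
    condition: str | None = None,
) -> list[ImageField]:
    """One list of fields per timepoint, inclusion fraction per trajectory.

    Field seeds derive deterministically from the template's seed (one
    draw per field, in timepoint-sorted order), so the whole time course
    is a pure function of the template.
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    for tp, frac in trajectory.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"inclusion fraction {frac} at {tp} outside [0, 1]")
    if fields_per_timepoint < 1:
        raise ValueError("fields_per_timepoint must be >=1")

    master = np.random.default_rng(template.seed)
    timepoints = sorted(trajectory)
    seeds = master.integers(0, 2**31 - 1, size=len(timepoints) * fields_per_timepoint)
    fields = []
    k = 0
    for tp in timepoints:
        for f in range(fields_per_timepoint):
            truth = dataclasses.replace(
                template, inclusion_fraction=float(trajectory[tp]), seed=int(seeds[k])
            )
            fld = gen_image_field(truth, shape=shape)
            fld.metadata.update(
                {"timepoint": tp, "field_id": f, "condition": condition}
            )
            k += 1
            fields.append(fld)
    return fields
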