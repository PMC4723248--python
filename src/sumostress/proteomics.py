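"""Differential sumoylation calling from label-free spectral counts.

Affinity-purified SUMO conjugates are identified by LC-MS/MS before and
after hyperosmotic stress (0 and 15 minutes).  Peptide-spectrum matches
arrive with a posterior identification probability (PeptideProphet score)
and a spectral count; spectral counts act as a semi-quantitative proxy for
protein abundance.  The calling procedure is:

1. discard peptide records with identification probability < 0.55,
2. sum spectral counts per protein within each sample,
3. per protein, compute the fold change of summed 15-minute counts over
   summed 0-minute counts and a two-tailed pooled-variance (homoscedastic)
   t-test on the per-replicate summed counts,
4. call a protein stress-enriched when fold change >= 3 and p <= 0.01
   (both boundaries inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Columns of a peptide identification table.
PEPTIDE_COLUMNS = (
    "protein_id",
    "peptide",
    "sample_id",
    "timepoint",
    "replicate",
    "probability",
    "spectral_count",
)

DEFAULT_MIN_PROBABILITY = 0.55
DEFAULT_FOLD_MIN = 3.0
DEFAULT_P_MAX = 0.01

#: Timepoints (minutes of hyperosmotic stress) compared by the caller.
TIMEPOINT_BASELINE = 0
TIMEPOINT_STRESS = 15


@dataclass(frozen=True)
class ProteinCountMatrix:
    """Proteins x samples summed spectral counts with group labels.

    ``counts`` is indexed by protein id with one column per sample id;
    every cell is defined (absent combinations are 0).  ``samples`` maps
    each sample id to its ``timepoint`` (minutes) and ``replicate`` label.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.is_unique:
            raise ValueError("sample ids (columns) must be unique")
        if not self.counts.index.is_unique:
            raise ValueError("protein ids (rows) must be unique")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")

    def samples_at(self, timepoint: int) -> list[str]:
        """Sample ids belonging to one timepoint group."""
        sel = self.samples.index[self.samples["timepoint"] == timepoint]
        return [s for s in self.counts.columns if s in set(sel)]


@dataclass(frozen=True)
class EnrichmentCall:
    """One protein's fold change, p value and pass/fail gate decision."""

    protein_id: str
    fold_change: float
    p_value: float
    passes: bool


def _validate_peptide_table(records: pd.DataFrame) -> None:
    missing = [c for c in PEPTIDE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    prob = records["probability"].to_numpy(dtype=float)
    if ((prob < 0) | (prob > 1) | ~np.isfinite(prob)).any():
        raise ValueError("identification probabilities must lie in [0, 1]")


def filter_peptides(
    records: pd.DataFrame, min_probability: float = DEFAULT_MIN_PROBABILITY
) -> pd.DataFrame:
    """Keep peptide records with identification probability >= cutoff.

    The boundary is inclusive: a record at exactly the cutoff is retained.
    Input row order is preserved.
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError("min_probability must lie in [0, 1]")
    _validate_peptide_table(records)
    kept = records[records["probability"] >= min_probability]
    logger.info(
        "peptide filter (p >= %.3g): kept %d of %d records",
        min_probability,
        len(kept),
        len(records),
    )
    return kept


def sum_counts(
    records: pd.DataFrame,
    proteins: list[str] | None = None,
    samples: pd.DataFrame | None = None,
) -> ProteinCountMatrix:
    """Sum spectral counts per (protein, sample).

    Duplicate (protein, peptide, sample) rows are summed.  ``proteins`` and
    ``samples`` optionally declare a roster so that proteins or samples
    without any record still appear (as all-zero rows/columns); ``samples``
    must then carry ``timepoint`` and ``replicate`` columns indexed by
    sample id.
    """
    _validate_peptide_table(records)
    if (records["spectral_count"].to_numpy() < 0).any():
        raise ValueError("spectral counts must be non-negative")

    sums = (
        records.groupby(["protein_id", "sample_id"], sort=True)["spectral_count"]
        .sum()
        .unstack(fill_value=0)
    )
    sums.columns.name = None
    sums.index.name = "protein_id"

    if samples is None:
        meta = (
            records[["sample_id", "timepoint", "replicate"]]
            .drop_duplicates()
            .set_index("sample_id")
        )
        if meta.index.has_duplicates:
            raise ValueError("inconsistent timepoint/replicate labels per sample")
    else:
        meta = samples
        sums = sums.reindex(columns=meta.index, fill_value=0)
    if proteins is not None:
        sums = sums.reindex(
            sums.index.union(pd.Index(proteins), sort=True), fill_value=0
        )
        sums.index.name = "protein_id"
    return ProteinCountMatrix(counts=sums.astype(np.int64), samples=meta)


def _pooled_t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-tailed homoscedastic two-sample t-test, rowwise.

    ``a`` and ``b`` are (proteins x replicates).  Rows where both groups
    have zero variance get p = 1 when the group means are equal (no
    evidence of change) and p = 0 otherwise (a change with no within-group
    noise).
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    p[degenerate & (m1 == m2)] = 1.0
    p[degenerate & (m1 != m2)] = 0.0
    return p


def test_enrichment(
    matrix: ProteinCountMatrix,
    baseline: int = TIMEPOINT_BASELINE,
    stress: int = TIMEPOINT_STRESS,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-protein fold change and homoscedastic t-test p value.

    Fold change is the ratio of summed counts, stress over baseline.  With
    ``pseudocount`` 0 (default), a zero baseline sum with a positive stress
    sum yields +inf, and two zero sums yield fold 1 with p 1.  The p value
    comes from a two-tailed pooled-variance t-test on the per-replicate
    summed counts.

    Returns a DataFrame indexed by protein id with columns
    ``sum_baseline``, ``sum_stress``, ``fold_change``, ``p_value``.
    """
    s0 = matrix.samples_at(baseline)
    s1 = matrix.samples_at(stress)
    if len(s0) < 2 or len(s1) < 2:
        raise ValueError(
            f"need >=2 replicates per timepoint group, got {len(s0)} at "
            f"{baseline} min and {len(s1)} at {stress} min"
        )
    a = matrix.counts[s0].to_numpy(dtype=float)
    b = matrix.counts[s1].to_numpy(dtype=float)
    sum0 = a.sum(axis=1)
    sum1 = b.sum(axis=1)

    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount > 0:
        fold = (sum1 + pseudocount) / (sum0 + pseudocount)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(
                sum0 > 0,
                sum1 / np.where(sum0 > 0, sum0, 1.0),
                np.where(sum1 > 0, np.inf, 1.0),
            )

    p = _pooled_t_pvalues(a, b)
    both_zero = (sum0 == 0) & (sum1 == 0)
    p[both_zero] = 1.0
    return pd.DataFrame(
        {
            "sum_baseline": sum0.astype(np.int64),
            "sum_stress": sum1.astype(np.int64),
            "fold_change": fold,
            "p_value": p,
        },
        index=matrix.counts.index,
    )


def call_enriched(
    results: pd.DataFrame,
    fold_min: float = DEFAULT_FOLD_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Apply the fold-change and p-value gate; both boundaries inclusive.

    A protein passes iff fold_change >= fold_min and p_value <= p_max.
    Output is sorted by descending fold change, ties broken by ascending
    p value then protein id.
    """
    calls = results.copy()
    calls["passes"] = (calls["fold_change"] >= fold_min) & (
        calls["p_value"] <= p_max
    )
    calls = (
        calls.rename_axis("protein_id")
        .reset_index()
        .sort_values(
            ["fold_change", "p_value", "protein_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        .set_index("protein_id")
    )
    logger.info(
        "enrichment gate (fold >= %g, p <= %g): %d of %d proteins pass",
        fold_min,
        p_max,
        int(calls["passes"].sum()),
        len(calls),
    )
    return calls


def run_ms_calling(
    records: pd.DataFrame,
    min_probability: float = DEFAULT_MIN_PROBABILITY,
    fold_min: float = DEFAULT_FOLD_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Full path: probability filter -> summed counts -> gate."""
    kept = filter_peptides(records, min_probability)
    matrix = sum_counts(kept)
    return call_enriched(test_enrichment(matrix), fold_min=fold_min, p_max=p_max)


def read_peptide_table(path) -> pd.DataFrame:
    """Read a tab-separated peptide identification table."""
    records = pd.read_csv(path, sep="\t")
    _validate_peptide_table(records)
    return records


def write_peptide_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write enrichment calls as TSV (protein_id, sums, fold, p, passes)."""
    calls.reset_index().to_csv(path, sep="\t", index=False)
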