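"""Per-module alteration-dose binning and dose-dependent marker tests.

For each gene module, every tumor is binned by its number of distinct
altered member genes — none, one, or >=2 — and the bins are tested
against histology (exact test on the 2 x k contingency table, the
Freeman–Halton extension of Fisher's exact test, with a seeded
Monte-Carlo fallback when the table space is too large to enumerate),
TMB (pairwise Welch t tests between bins), and PD-L1 level
(Pearson chi-squared on the 3-level x bin table, no continuity
correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .io_model import (
    GeneAlterationMatrix,
    Histology,
    Pdl1Level,
    SampleRecord,
    pdl1_level,
)

__all__ = [
    "DoseBin",
    "DoseTestResult",
    "assign_dose_bins",
    "exact_2xc_test",
    "test_histology_dose",
    "test_tmb_dose",
    "test_pdl1_dose",
]

BIN_NAMES = ("none", "one", "two_plus")
ENUMERATION_LIMIT = 10_000_000
MC_TABLES = 100_000


@dataclass
class DoseBin:
    sample_id: str
    module_id: int
    bin: str  # "none" | "one" | "two_plus"


@dataclass
class DoseTestResult:
    module_id: int
    variable: str  # "histology" | "tmb" | "pdl1"
    bin_n: dict[str, int]
    global_p: float | None = None
    statistic: float | None = None
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)
    # pairwise entries: (bin_a, bin_b, estimate, p)
    summaries: dict[str, dict] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def assign_dose_bins(
    module_genes: Sequence[str],
    matrix: GeneAlterationMatrix,
    module_id: int = 0,
) -> list[DoseBin]:
    """Bin every sample by its count of distinct altered member genes."""
    missing = [g for g in module_genes if g not in matrix.genes]
    if missing:
        raise KeyError(f"module genes absent from matrix: {missing}")
    counts = np.zeros(len(matrix.samples), dtype=int)
    for g in module_genes:
        counts += matrix.gene_column(g).astype(int)
    bins = np.where(counts == 0, "none", np.where(counts == 1, "one", "two_plus"))
    return [
        DoseBin(sid, module_id, b) for sid, b in zip(matrix.samples, bins)
    ]


# ---------------------------------------------------------------------------
# exact 2 x c test (Freeman–Halton)
# ---------------------------------------------------------------------------

def exact_2xc_test(
    table: Sequence[Sequence[int]],
    seed: int = 0,
    enumeration_limit: int = ENUMERATION_LIMIT,
    n_mc: int = MC_TABLES,
) -> float:
    """Two-sided exact p for a 2 x c table, probability-mass convention.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (relative tolerance 1e-7).  When the margin-constrained table count
    exceeds ``enumeration_limit``, falls back to seeded Monte Carlo
    (``n_mc`` tables drawn from the multivariate hypergeometric null),
    reporting (exceedances + 1) / (draws + 1).
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise ValueError("expected a 2 x c table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    cols = arr.sum(axis=0)
    keep = cols > 0
    arr = arr[:, keep]
    cols = cols[keep]
    if arr.shape[1] < 2 or arr.sum(axis=1).min() == 0:
        return 1.0  # degenerate margins admit a single table
    r1 = int(arr[0].sum())
    n = int(arr.sum())

    def logprob(a: np.ndarray) -> np.ndarray:
        # a: (..., c) first-row counts; log P(table | margins)
        lp = -(
            gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
        ) * np.ones(a.shape[:-1])
        for j, cj in enumerate(cols):
            aj = a[..., j]
            lp += gammaln(cj + 1) - gammaln(aj + 1) - gammaln(cj - aj + 1)
        return lp

    obs_lp = float(logprob(arr[0].astype(float)))
    tol = math.log1p(1e-7)

    # count margin-compatible tables: free cells are columns 0..c-2
    est_tables = float(np.prod([min(r1, cj) + 1 for cj in cols[:-1]]))
    if est_tables <= enumeration_limit:
        grids = np.meshgrid(
            *[np.arange(min(r1, cj) + 1) for cj in cols[:-1]], indexing="ij"
        )
        free = np.stack([g.ravel() for g in grids], axis=-1)
        last = r1 - free.sum(axis=-1)
        valid = (last >= 0) & (last <= cols[-1])
        a = np.concatenate([free[valid], last[valid, None]], axis=-1).astype(float)
        lps = logprob(a)
        mask = lps <= obs_lp + tol
        # log-sum-exp over the accepted tables
        m = lps[mask]
        return float(min(1.0, np.exp(m.max()) * np.exp(m - m.max()).sum())) \
            if m.size else 0.0

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, r1, size=n_mc).astype(float)
    lps = logprob(draws)
    exceed = int(np.sum(lps <= obs_lp + tol))
    return (exceed + 1) / (n_mc + 1)


def _bins_by_sample(bins: Sequence[DoseBin]) -> dict[str, str]:
    return {b.sample_id: b.bin for b in bins}


def test_histology_dose(
    bins: Sequence[DoseBin],
    samples: Sequence[SampleRecord],
    seed: int = 0,
) -> DoseTestResult:
    """Exact test of histology (adeno vs squamous) across dose bins.

    Empty bins are dropped with a note; a single non-empty bin gives
    p = 1 by convention.  With two non-empty bins this reduces to the
    2x2 Fisher's exact test.
    """
    module_id = bins[0].module_id if bins else 0
    bmap = _bins_by_sample(bins)
    table = {b: [0, 0] for b in BIN_NAMES}
    for s in samples:
        b = bmap.get(s.sample_id)
        if b is None:
            continue
        if s.histology is Histology.ADENOCARCINOMA:
            table[b][0] += 1
        elif s.histology is Histology.SQUAMOUS:
            table[b][1] += 1
    result = DoseTestResult(
        module_id=module_id,
        variable="histology",
        bin_n={b: sum(table[b]) for b in BIN_NAMES},
    )
    nonempty = [b for b in BIN_NAMES if sum(table[b]) > 0]
    for b in BIN_NAMES:
        if sum(table[b]) == 0:
            result.notes.append(f"bin {b} empty; dropped")
        else:
            total = sum(table[b])
            result.summaries[b] = {
                "frac_adeno": table[b][0] / total,
                "frac_squam": table[b][1] / total,
            }
    if len(nonempty) < 2:
        result.global_p = 1.0
        return result
    arr = np.array([[table[b][0] for b in nonempty],
                    [table[b][1] for b in nonempty]])
    result.global_p = exact_2xc_test(arr, seed=seed)
    return result


def test_tmb_dose(
    bins: Sequence[DoseBin], samples: Sequence[SampleRecord]
) -> DoseTestResult:
    """Pairwise Welch t tests of TMB between dose bins.

    Contrasts with fewer than two TMB values on either side are skipped
    with a note.  Estimates are mean differences (first minus second
    bin); per-bin medians are reported for display.
    """
    module_id = bins[0].module_id if bins else 0
    bmap = _bins_by_sample(bins)
    values: dict[str, list[float]] = {b: [] for b in BIN_NAMES}
    for s in samples:
        b = bmap.get(s.sample_id)
        if b is not None and s.tmb is not None:
            values[b].append(s.tmb)
    result = DoseTestResult(
        module_id=module_id,
        variable="tmb",
        bin_n={b: len(values[b]) for b in BIN_NAMES},
    )
    for b in BIN_NAMES:
        if values[b]:
            result.summaries[b] = {
                "median": float(np.median(values[b])),
                "mean": float(np.mean(values[b])),
            }
    for a, b in (("none", "one"), ("one", "two_plus"), ("none", "two_plus")):
        if len(values[a]) < 2 or len(values[b]) < 2:
            result.notes.append(f"contrast {a} vs {b} skipped: <2 values")
            continue
        t = stats.ttest_ind(values[a], values[b], equal_var=False)
        est = float(np.mean(values[a]) - np.mean(values[b]))
        result.pairwise.append((a, b, est, float(t.pvalue)))
    return result


def test_pdl1_dose(
    bins: Sequence[DoseBin], samples: Sequence[SampleRecord]
) -> DoseTestResult:
    """Pearson chi-squared of PD-L1 level (3 levels) across dose bins.

    No continuity correction; df = (levels-1)(bins-1).  Raises if fewer
    than two bins have PD-L1 data; warns when any expected count is
    below 5.
    """
    module_id = bins[0].module_id if bins else 0
    bmap = _bins_by_sample(bins)
    level_order = [Pdl1Level.NEGATIVE, Pdl1Level.LOW, Pdl1Level.HIGH]
    counts: dict[str, list[int]] = {b: [0, 0, 0] for b in BIN_NAMES}
    for s in samples:
        b = bmap.get(s.sample_id)
        lv = pdl1_level(s.pdl1_tps)
        if b is not None and lv is not None:
            counts[b][level_order.index(lv)] += 1
    result = DoseTestResult(
        module_id=module_id,
        variable="pdl1",
        bin_n={b: sum(counts[b]) for b in BIN_NAMES},
    )
    nonempty = [b for b in BIN_NAMES if sum(counts[b]) > 0]
    for b in nonempty:
        total = sum(counts[b])
        result.summaries[b] = {
            lv.value: counts[b][i] / total for i, lv in enumerate(level_order)
        }
    if len(nonempty) < 2:
        raise ValueError("chi-squared test needs at least two non-empty bins")
    arr = np.array([counts[b] for b in nonempty]).T  # levels x bins
    arr = arr[arr.sum(axis=1) > 0, :]  # drop empty levels
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"module {module_id}: chi-squared expected count below 5",
            stacklevel=2,
        )
    result.statistic = float(chi2)
    result.global_p = float(p)
    return result
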