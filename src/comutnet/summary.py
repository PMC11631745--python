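"""Cohort characteristics table and adenocarcinoma-vs-squamous comparisons.

Reproduces the standard clinical-cohort summary: per-variable counts and
percents (with per-variable denominators — samples missing a marker are
dropped only from that marker's rows), means with standard deviations
for quantitative variables, and an unadjusted comparison p-value per row
(two-sided Fisher's exact test for each category level vs the rest,
least squares — equivalently the pooled two-sample t test — for
quantitative variables).

A packaged fixture transcribes the printed counts of a 7,606-tumor
NSCLC comprehensive-genomic-profiling cohort, used to check that the
percent-regeneration logic reproduces every printed percent at its
printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .io_model import (
    AlterationRecord,
    Histology,
    MsiStatus,
    Pdl1Level,
    SampleRecord,
    Sex,
    SpecimenSite,
    Stage,
    Tier,
    TmbLevel,
    pdl1_level,
    round_half_up,
    tmb_level,
)

__all__ = [
    "SummaryRow",
    "summarize_cohort",
    "compare_categorical",
    "compare_quantitative",
    "load_table1_fixture",
    "fixture_percent_errors",
    "write_summary_tsv",
]

AGE_BANDS = [
    ("<=40", -math.inf, 40.0),
    ("41-50", 40.0, 50.0),
    ("51-60", 50.0, 60.0),
    ("61-70", 60.0, 70.0),
    ("71-80", 70.0, 80.0),
    ("81-90", 80.0, 90.0),
    (">90", 90.0, math.inf),
]


@dataclass
class SummaryRow:
    variable: str
    level: str | None
    n_all: int
    n_adeno: int
    n_squam: int
    denom_all: int
    denom_adeno: int
    denom_squam: int
    pct_all: float | None = None
    pct_adeno: float | None = None
    pct_squam: float | None = None
    mean_sd_all: tuple[float, float] | None = None
    mean_sd_adeno: tuple[float, float] | None = None
    mean_sd_squam: tuple[float, float] | None = None
    p_value: float | None = None


def compare_categorical(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p of a 2x2 level-vs-rest x histology table.

    Degenerate margins (an empty row or column) give p = 1.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def compare_quantitative(
    values: Sequence[float], squamous: Sequence[bool]
) -> tuple[float, float]:
    """Least squares of a quantitative variable on a squamous indicator.

    Returns (coefficient, p).  The coefficient is the squamous-minus-
    adenocarcinoma mean difference and the t-based p equals the pooled-
    variance two-sample t test.  Each group needs at least two values.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(squamous, dtype=float)
    if np.sum(g == 1.0) < 2 or np.sum(g == 0.0) < 2:
        raise ValueError("need at least two values per group")
    X = np.column_stack([np.ones_like(y), g])
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def _count_row(
    variable: str,
    level: str,
    flag_all: np.ndarray,
    present: np.ndarray,
    squam: np.ndarray,
    decimals: int = 1,
) -> SummaryRow:
    """Build one categorical row, percents on per-variable denominators."""
    adeno = ~squam
    n_all = int(np.sum(flag_all & present))
    n_a = int(np.sum(flag_all & present & adeno))
    n_s = int(np.sum(flag_all & present & squam))
    d_all = int(present.sum())
    d_a = int(np.sum(present & adeno))
    d_s = int(np.sum(present & squam))
    table = [
        [n_a, d_a - n_a],
        [n_s, d_s - n_s],
    ]
    return SummaryRow(
        variable=variable,
        level=level,
        n_all=n_all,
        n_adeno=n_a,
        n_squam=n_s,
        denom_all=d_all,
        denom_adeno=d_a,
        denom_squam=d_s,
        pct_all=round_half_up(100.0 * n_all / d_all, decimals) if d_all else None,
        pct_adeno=round_half_up(100.0 * n_a / d_a, decimals) if d_a else None,
        pct_squam=round_half_up(100.0 * n_s / d_s, decimals) if d_s else None,
        p_value=compare_categorical(table) if d_a and d_s else None,
    )


def _mean_row(
    variable: str, values: np.ndarray, present: np.ndarray, squam: np.ndarray
) -> SummaryRow:
    adeno = ~squam
    def ms(mask: np.ndarray) -> tuple[float, float] | None:
        v = values[mask & present]
        if v.size == 0:
            return None
        return float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    p = None
    if np.sum(present & adeno) >= 2 and np.sum(present & squam) >= 2:
        _, p = compare_quantitative(values[present], squam[present])
    return SummaryRow(
        variable=variable,
        level=None,
        n_all=int(present.sum()),
        n_adeno=int(np.sum(present & adeno)),
        n_squam=int(np.sum(present & squam)),
        denom_all=int(present.sum()),
        denom_adeno=int(np.sum(present & adeno)),
        denom_squam=int(np.sum(present & squam)),
        mean_sd_all=ms(np.ones_like(present)),
        mean_sd_adeno=ms(adeno),
        mean_sd_squam=ms(squam),
        p_value=p,
    )


def summarize_cohort(
    samples: Sequence[SampleRecord],
    alterations: Sequence[AlterationRecord],
) -> list[SummaryRow]:
    """Emit the cohort-characteristics rows in clinical-table order.

    Order: sex, age (mean±SD and bands), specimen site, known clinical
    stage, number of detected pathogenic alterations (mean±SD), tier
    positivity, TMB (mean±SD and levels), PD-L1 (mean±SD and levels),
    MSI.  Percents use per-variable denominators (non-missing samples),
    rounded half-up to one decimal.
    """
    n = len(samples)
    squam = np.array([s.histology is Histology.SQUAMOUS for s in samples])
    all_present = np.ones(n, dtype=bool)
    rows: list[SummaryRow] = []

    # sex
    sex_present = np.array([s.sex is not Sex.UNKNOWN for s in samples])
    for lv in (Sex.FEMALE, Sex.MALE):
        flag = np.array([s.sex is lv for s in samples])
        rows.append(_count_row("sex", lv.value, flag, sex_present, squam))

    # age: mean ± sd, then bands
    age = np.array([math.nan if s.age is None else s.age for s in samples])
    age_present = ~np.isnan(age)
    rows.append(_mean_row("age", age, age_present, squam))
    for name, lo, hi in AGE_BANDS:
        flag = age_present & (age > lo) & (age <= hi)
        rows.append(_count_row("age_group", name, flag, age_present, squam))

    # specimen site (percents on the full cohort, site never missing here)
    for lv in (SpecimenSite.PRIMARY, SpecimenSite.ADVANCED, SpecimenSite.METASTATIC):
        flag = np.array([s.specimen_site is lv for s in samples])
        rows.append(_count_row("specimen_site", lv.value, flag, all_present, squam))

    # clinical stage (known only)
    stage_known = np.array([s.stage is not Stage.UNKNOWN for s in samples])
    rows.append(_count_row("stage_known", "known", stage_known, all_present, squam))
    for lv in (Stage.I, Stage.II, Stage.III, Stage.IV):
        flag = np.array([s.stage is lv for s in samples])
        rows.append(_count_row("stage", lv.value, flag, stage_known, squam))

    # number of detected pathogenic alterations (samples with >=1)
    counts = {s.sample_id: 0 for s in samples}
    for a in alterations:
        if a.sample_id in counts:
            counts[a.sample_id] += 1
    n_alts = np.array([float(counts[s.sample_id]) for s in samples])
    alt_present = n_alts > 0
    rows.append(_mean_row("n_alterations", n_alts, alt_present, squam))

    # tier positivity: any alteration of the tier per sample
    tiers_by_sample: dict[str, set[Tier]] = {s.sample_id: set() for s in samples}
    for a in alterations:
        if a.sample_id in tiers_by_sample:
            tiers_by_sample[a.sample_id].add(a.tier)
    for tier in (Tier.GUIDELINE_INDICATED, Tier.TRIAL_OR_OTHER_TUMOR,
                 Tier.PATHOGENIC_UNKNOWN):
        flag = np.array([tier in tiers_by_sample[s.sample_id] for s in samples])
        rows.append(_count_row("tier_positive", tier.value, flag, all_present, squam))

    # TMB
    tmb = np.array([math.nan if s.tmb is None else s.tmb for s in samples])
    tmb_present = ~np.isnan(tmb)
    rows.append(_mean_row("tmb", tmb, tmb_present, squam))
    levels = [tmb_level(s.tmb) for s in samples]
    for lv in (TmbLevel.VERY_HIGH, TmbLevel.HIGH, TmbLevel.NOT_HIGH):
        flag = np.array([x is lv for x in levels])
        rows.append(_count_row("tmb_level", lv.value, flag, tmb_present, squam))

    # PD-L1
    tps = np.array([math.nan if s.pdl1_tps is None else s.pdl1_tps for s in samples])
    tps_present = ~np.isnan(tps)
    rows.append(_mean_row("pdl1_tps", tps, tps_present, squam))
    plevels = [pdl1_level(s.pdl1_tps) for s in samples]
    for lv in (Pdl1Level.HIGH, Pdl1Level.LOW, Pdl1Level.NEGATIVE):
        flag = np.array([x is lv for x in plevels])
        rows.append(_count_row("pdl1_level", lv.value, flag, tps_present, squam))

    # MSI
    msi_present = np.array([s.msi is not MsiStatus.MISSING for s in samples])
    for lv in (MsiStatus.HIGH, MsiStatus.STABLE):
        flag = np.array([s.msi is lv for s in samples])
        rows.append(_count_row("msi", lv.value, flag, msi_present, squam))

    return rows


# ---------------------------------------------------------------------------
# printed-table fixture
# ---------------------------------------------------------------------------

def load_table1_fixture() -> pd.DataFrame:
    """The packaged transcription of the printed cohort-summary counts.

    Columns: variable, level, and for each of the all / adenocarcinoma /
    squamous columns the count, per-variable denominator, and the
    percent exactly as printed (a string preserving printed precision).
    """
    path = Path(__file__).parent / "fixtures" / "table1_counts.tsv"
    return pd.read_csv(path, sep="\t", dtype=str)


def fixture_percent_errors() -> pd.DataFrame:
    """Regenerate every fixture percent from counts; compare with printed.

    For each (row, cohort-column) with a printed percent, recomputes
    100*n/denominator rounded half-up to the printed number of decimals
    and reports the regenerated value, printed value, and difference.
    """
    fixture = load_table1_fixture()
    records = []
    for _, row in fixture.iterrows():
        for col in ("all", "adeno", "squam"):
            printed = row[f"pct_{col}"]
            if not isinstance(printed, str) or printed.strip() == "":
                continue
            n = int(row[f"n_{col}"])
            denom = int(row[f"denom_{col}"])
            decimals = len(printed.split(".")[1]) if "." in printed else 0
            regenerated = round_half_up(100.0 * n / denom, decimals)
            records.append(
                {
                    "variable": row["variable"],
                    "level": row["level"],
                    "cohort": col,
                    "printed": float(printed),
                    "regenerated": regenerated,
                    "abs_error": abs(regenerated - float(printed)),
                }
            )
    return pd.DataFrame.from_records(records)


def write_summary_tsv(rows: Sequence[SummaryRow], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "variable\tlevel\tn_all\tpct_all\tmean_sd_all\tn_adeno\tpct_adeno\t"
            "mean_sd_adeno\tn_squam\tpct_squam\tmean_sd_squam\tp_value\n"
        )
        for r in rows:
            def fmt_ms(ms):
                return "" if ms is None else f"{ms[0]:.1f}±{ms[1]:.1f}"
            handle.write(
                f"{r.variable}\t{r.level or ''}\t{r.n_all}\t"
                f"{'' if r.pct_all is None else r.pct_all}\t{fmt_ms(r.mean_sd_all)}\t"
                f"{r.n_adeno}\t{'' if r.pct_adeno is None else r.pct_adeno}\t"
                f"{fmt_ms(r.mean_sd_adeno)}\t{r.n_squam}\t"
                f"{'' if r.pct_squam is None else r.pct_squam}\t"
                f"{fmt_ms(r.mean_sd_squam)}\t"
                f"{'' if r.p_value is None else f'{r.p_value:.3g}'}\n"
            )
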