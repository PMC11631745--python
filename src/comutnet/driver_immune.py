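"""Driver-group assignment and driver vs immunotherapy-marker tests.

Tumors are grouped per driver gene (ALK, EGFR, MET, BRAF, ROS1, ERBB2,
KRAS) by a configurable taxonomy of named, first-match-wins variant
groups (e.g. EML4-ALK fusion vs other ALK fusion vs other ALK
alteration); tumors with no alteration in any taxonomy gene form a
single cohort-global "driver gene negative" reference group.

TMB (mutations/Mb, untransformed) is compared between groups by least
squares with a histology covariate; every pairwise group contrast gets
a t-based p-value, Bonferroni-corrected within the gene.

PD-L1 tumor proportion score is a 3-level ordinal marker
(negative <1% / low 1-49% / high >=50%); each pairwise group contrast
is tested on two clinical dichotomies (high vs rest, positive vs
negative) with Firth-penalized logistic regression — the Jeffreys-prior
penalty keeps estimates finite under the complete separation that small
driver groups routinely produce — and a penalized likelihood-ratio test
on the group indicator.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import linalg as sla
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm

from .io_model import (
    AltClass,
    AlterationRecord,
    Histology,
    Pdl1Level,
    SampleRecord,
    Tier,
    pdl1_level,
)

__all__ = [
    "GroupRule",
    "DriverTaxonomy",
    "DriverAssignments",
    "GroupTestResult",
    "FirthFit",
    "DRIVER_NEGATIVE",
    "load_taxonomy",
    "default_taxonomy",
    "assign_driver_groups",
    "tmb_group_test",
    "firth_fit",
    "penalized_lrt",
    "pdl1_group_test",
]

DRIVER_NEGATIVE = "driver_gene_negative"


@dataclass(frozen=True)
class GroupRule:
    """One named variant group: all specified criteria must match a record."""

    name: str
    alt_classes: tuple[AltClass, ...] | None = None
    variant_contains: str | None = None
    variant_equals: tuple[str, ...] | None = None
    tiers: tuple[Tier, ...] | None = None

    def matches(self, record: AlterationRecord) -> bool:
        if self.alt_classes is not None and record.alt_class not in self.alt_classes:
            return False
        if (
            self.variant_contains is not None
            and self.variant_contains.lower() not in record.variant_label.lower()
        ):
            return False
        if self.variant_equals is not None and record.variant_label.upper() not in {
            v.upper() for v in self.variant_equals
        }:
            return False
        if self.tiers is not None and record.tier not in self.tiers:
            return False
        return True


@dataclass
class DriverTaxonomy:
    """Ordered, first-match-wins group rules per driver gene."""

    genes: dict[str, list[GroupRule]]

    def gene_list(self) -> list[str]:
        return list(self.genes)


@dataclass
class DriverAssignments:
    """Per-gene sample -> group-name maps plus the global driver-negative set."""

    per_gene: dict[str, dict[str, str]]
    driver_negative: set[str]

    def groups(self, gene: str) -> dict[str, str]:
        return self.per_gene[gene]


@dataclass
class GroupTestResult:
    gene: str
    group_a: str
    group_b: str
    marker: str  # "tmb", "pdl1_high_vs_rest", "pdl1_pos_vs_neg"
    estimate: float  # mean difference (TMB) or log-OR (PD-L1)
    p_raw: float
    p_bonferroni: float
    n_a: int
    n_b: int
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def _rule_from_dict(d: Mapping) -> GroupRule:
    return GroupRule(
        name=str(d["name"]),
        alt_classes=tuple(AltClass.parse(c) for c in d["alt_class"])
        if "alt_class" in d
        else None,
        variant_contains=d.get("variant_contains"),
        variant_equals=tuple(d["variant_equals"]) if "variant_equals" in d else None,
        tiers=tuple(Tier.parse(t) for t in d["tier"]) if "tier" in d else None,
    )


def load_taxonomy(path: str | Path) -> DriverTaxonomy:
    """Load a driver-group taxonomy from YAML."""
    with Path(path).open(encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    genes = {
        gene: [_rule_from_dict(g) for g in spec["groups"]]
        for gene, spec in raw["genes"].items()
    }
    return DriverTaxonomy(genes)


def default_taxonomy() -> DriverTaxonomy:
    """The packaged default taxonomy (driver groups of the seven NSCLC genes)."""
    here = Path(__file__).parent / "fixtures" / "driver_taxonomy.yaml"
    return load_taxonomy(here)


def assign_driver_groups(
    alterations: Sequence[AlterationRecord],
    samples: Sequence[SampleRecord],
    taxonomy: DriverTaxonomy,
) -> DriverAssignments:
    """Map each sample, per gene, to its first matching variant group.

    A sample altered in a taxonomy gene but matching no rule falls into
    "other <gene> alteration".  The driver-negative set — samples with
    no alteration in any taxonomy gene — is computed once, cohort-wide.
    """
    by_gene: dict[str, dict[str, list[AlterationRecord]]] = {
        g: {} for g in taxonomy.genes
    }
    samples_with_any: set[str] = set()
    for rec in alterations:
        if rec.gene in by_gene:
            by_gene[rec.gene].setdefault(rec.sample_id, []).append(rec)
            samples_with_any.add(rec.sample_id)
    per_gene: dict[str, dict[str, str]] = {}
    for gene, rules in taxonomy.genes.items():
        assignment: dict[str, str] = {}
        for sid, recs in by_gene[gene].items():
            group = None
            for rule in rules:
                if any(rule.matches(r) for r in recs):
                    group = rule.name
                    break
            assignment[sid] = group or f"other {gene} alteration"
        per_gene[gene] = assignment
    negative = {s.sample_id for s in samples} - samples_with_any
    return DriverAssignments(per_gene=per_gene, driver_negative=negative)


# ---------------------------------------------------------------------------
# TMB group tests (least squares with histology covariate)
# ---------------------------------------------------------------------------

def _collect_groups(
    samples: Sequence[SampleRecord],
    assignments: DriverAssignments,
    gene: str,
    marker: str,
) -> dict[str, list[SampleRecord]]:
    """Samples per group (taxonomy groups + driver-negative), marker present."""
    by_id = {s.sample_id: s for s in samples}
    groups: dict[str, list[SampleRecord]] = {}
    for sid, group in assignments.groups(gene).items():
        s = by_id.get(sid)
        if s is None:
            continue
        value = s.tmb if marker == "tmb" else s.pdl1_tps
        if value is None:
            continue
        groups.setdefault(group, []).append(s)
    negatives = [
        by_id[sid]
        for sid in assignments.driver_negative
        if sid in by_id
        and (by_id[sid].tmb if marker == "tmb" else by_id[sid].pdl1_tps) is not None
    ]
    if negatives:
        groups[DRIVER_NEGATIVE] = negatives
    return groups


def _design(
    members: Sequence[tuple[str, SampleRecord]],
    group_order: Sequence[str],
    include_histology: bool,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicators (ref = first group) + squamous indicator."""
    cols = [np.ones(len(members))]
    names = ["intercept"]
    for g in group_order[1:]:
        cols.append(np.array([1.0 if gm == g else 0.0 for gm, _ in members]))
        names.append(f"group[{g}]")
    if include_histology:
        squam = np.array(
            [1.0 if s.histology is Histology.SQUAMOUS else 0.0 for _, s in members]
        )
        if 0.0 < squam.mean() < 1.0:
            cols.append(squam)
            names.append("histology[squamous]")
    return np.column_stack(cols), names


def tmb_group_test(
    samples: Sequence[SampleRecord],
    assignments: DriverAssignments,
    gene: str,
    include_histology: bool = True,
    bonferroni_n: int | None = None,
) -> list[GroupTestResult]:
    """All pairwise TMB contrasts between a gene's groups (plus driver-negative).

    Fits one least-squares model of TMB on group indicators and a
    squamous-histology indicator, then tests each pairwise difference of
    group coefficients with its t statistic.  Bonferroni correction uses
    the number of contrasts within the gene unless ``bonferroni_n``
    overrides it.  Groups with fewer than two TMB values are skipped.
    """
    groups = _collect_groups(samples, assignments, gene, "tmb")
    usable = {g: mem for g, mem in groups.items() if len(mem) >= 2}
    if len(usable) < 2:
        return []
    order = sorted(usable)
    members = [(g, s) for g in order for s in usable[g]]
    y = np.array([s.tmb for _, s in members], dtype=float)
    X, names = _design(members, order, include_histology)
    fit = sm.OLS(y, X).fit()

    def coef_vec(group: str) -> np.ndarray:
        vec = np.zeros(len(names))
        if group != order[0]:
            vec[names.index(f"group[{group}]")] = 1.0
        return vec

    contrasts = list(itertools.combinations(order, 2))
    n_tests = bonferroni_n if bonferroni_n is not None else len(contrasts)
    results = []
    medians = {g: float(np.median([s.tmb for s in usable[g]])) for g in usable}
    for a, b in contrasts:
        L = coef_vec(a) - coef_vec(b)
        test = fit.t_test(L)
        p = float(np.squeeze(test.pvalue))
        results.append(
            GroupTestResult(
                gene=gene,
                group_a=a,
                group_b=b,
                marker="tmb",
                estimate=float(np.squeeze(test.effect)),
                p_raw=p,
                p_bonferroni=min(1.0, p * n_tests),
                n_a=len(usable[a]),
                n_b=len(usable[b]),
                detail={"median_a": medians[a], "median_b": medians[b]},
            )
        )
    return results


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

@dataclass
class FirthFit:
    coef: np.ndarray
    loglik_penalized: float
    converged: bool
    n_iter: int


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood written to stay finite for large |eta|
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    W = p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -math.inf
    return ll + 0.5 * logdet


def firth_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> FirthFit:
    """Jeffreys-penalized (Firth) logistic regression.

    Maximizes l(beta) + 0.5 * log det I(beta) by Newton iteration on the
    hat-diagonal-adjusted score U*_j = sum_i (y_i - p_i + h_i (1/2 -
    p_i)) x_ij, with step-halving whenever a step would lower the
    penalized log-likelihood.  Converges when max |U*| < ``tol`` (or
    after ``max_iter`` iterations).  Estimates stay finite under
    complete separation.  The design must have full column rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y lengths differ")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < k:
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        raise ValueError(
            f"design matrix is rank deficient; collinear column(s) near "
            f"index {sorted(piv[np.linalg.matrix_rank(X):].tolist())}"
        )
    def modified_score(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = expit(X @ b)
        W = p * (1.0 - p)
        info = X.T @ (X * W[:, None])
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W  # hat diagonal
        return X.T @ (y - p + h * (0.5 - p)), info_inv

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, info_inv = modified_score(beta)
        score_norm = float(np.max(np.abs(score)))
        if score_norm < tol:
            # terminal refinement: a few more contracting steps push the
            # residual score far below the stopping tolerance
            for _ in range(10):
                step = info_inv @ score
                for _ in range(25):
                    new_score, new_inv = modified_score(beta + step)
                    if float(np.max(np.abs(new_score))) < score_norm:
                        break
                    step *= 0.5
                else:
                    break
                beta = beta + step
                score, info_inv = new_score, new_inv
                score_norm = float(np.max(np.abs(score)))
                if score_norm < tol * 1e-6:
                    break
            converged = True
            break
        # Step-halve until the modified score contracts; the expected-
        # information Hessian under-curves the penalized score on tiny
        # samples, where the full step can oscillate without this.
        step = info_inv @ score
        for _ in range(25):
            new_beta = beta + step
            new_norm = float(np.max(np.abs(modified_score(new_beta)[0])))
            if new_norm < score_norm:
                break
            step *= 0.5
        beta = new_beta
    if not converged:
        warnings.warn("firth_fit did not converge", stacklevel=2)
    return FirthFit(
        coef=beta,
        loglik_penalized=_penalized_loglik(X, y, beta),
        converged=converged,
        n_iter=it,
    )


def penalized_lrt(
    X_full: np.ndarray,
    X_null: np.ndarray,
    y: np.ndarray,
    **fit_kwargs,
) -> tuple[float, int, float]:
    """Penalized likelihood-ratio test of nested Firth fits.

    The null design must be a column subset of the full design.  The
    statistic 2*(pl_full - pl_null) is clipped at zero (the penalized
    likelihoods are maximized, so a negative value can only be numerical
    noise) and referred to chi-squared with df = column difference.
    """
    X_full = np.asarray(X_full, dtype=float)
    X_null = np.asarray(X_null, dtype=float)
    full_cols = {tuple(np.round(X_full[:, j], 12)) for j in range(X_full.shape[1])}
    for j in range(X_null.shape[1]):
        if tuple(np.round(X_null[:, j], 12)) not in full_cols:
            raise ValueError("null design is not nested in the full design")
    df = X_full.shape[1] - X_null.shape[1]
    if df <= 0:
        raise ValueError("full design must have more columns than the null")
    fit_full = firth_fit(X_full, y, **fit_kwargs)
    fit_null = firth_fit(X_null, y, **fit_kwargs)
    stat = max(0.0, 2.0 * (fit_full.loglik_penalized - fit_null.loglik_penalized))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# PD-L1 group tests
# ---------------------------------------------------------------------------

PDL1_DICHOTOMIES = {
    "pdl1_high_vs_rest": lambda lv: 1.0 if lv is Pdl1Level.HIGH else 0.0,
    "pdl1_pos_vs_neg": lambda lv: 0.0 if lv is Pdl1Level.NEGATIVE else 1.0,
}


def pdl1_group_test(
    samples: Sequence[SampleRecord],
    assignments: DriverAssignments,
    gene: str,
    include_histology: bool = True,
    bonferroni_n: int | None = None,
) -> list[GroupTestResult]:
    """Firth-penalized PD-L1 contrasts between a gene's groups.

    For every pairwise group contrast and each of two clinical
    dichotomies (TPS >=50% vs rest; TPS >=1% vs negative), fits Firth
    logistic models with and without the group indicator (histology
    covariate kept in both) and reports the penalized LRT p together
    with the group log-OR.  Bonferroni multiplier defaults to
    contrasts x dichotomies within the gene.  A dichotomy with no
    events, or all events, in a contrast's two groups is skipped.
    """
    groups = _collect_groups(samples, assignments, gene, "pdl1")
    usable = {g: mem for g, mem in groups.items() if len(mem) >= 2}
    if len(usable) < 2:
        return []
    order = sorted(usable)
    contrasts = list(itertools.combinations(order, 2))
    n_tests = (
        bonferroni_n if bonferroni_n is not None
        else len(contrasts) * len(PDL1_DICHOTOMIES)
    )
    level_freq = {
        g: {
            lv.value: sum(1 for s in mem if pdl1_level(s.pdl1_tps) is lv) / len(mem)
            for lv in Pdl1Level
        }
        for g, mem in usable.items()
    }
    results: list[GroupTestResult] = []
    for a, b in contrasts:
        members = [(g, s) for g in (a, b) for s in usable[g]]
        for marker, encode in PDL1_DICHOTOMIES.items():
            y = np.array(
                [encode(pdl1_level(s.pdl1_tps)) for _, s in members], dtype=float
            )
            if y.sum() == 0.0 or y.sum() == len(y):
                continue  # no events (or all events) in both groups
            X_full, names = _design(members, (a, b), include_histology)
            group_col = names.index(f"group[{b}]")
            X_null = np.delete(X_full, group_col, axis=1)
            stat, df, p = penalized_lrt(X_full, X_null, y)
            coef = firth_fit(X_full, y).coef[group_col]
            results.append(
                GroupTestResult(
                    gene=gene,
                    group_a=a,
                    group_b=b,
                    marker=marker,
                    estimate=-float(coef),  # log-OR of a relative to b
                    p_raw=p,
                    p_bonferroni=min(1.0, p * n_tests),
                    n_a=len(usable[a]),
                    n_b=len(usable[b]),
                    detail={
                        "lrt_stat": stat,
                        "df": df,
                        "levels_a": level_freq[a],
                        "levels_b": level_freq[b],
                    },
                )
            )
    return results
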