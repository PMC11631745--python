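"""Seeded synthetic NSCLC-style cohort generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline can be exercised and its parameter recovery measured
without any patient data:

* per-histology driver-gene prevalences with drivers mutually exclusive
  by construction (each sample carries at most one driver, drawn
  categorically);
* planted co-occurrence modules via a latent-Bernoulli mixture — module
  genes are conditionally independent given a latent "module on" state,
  which induces a closed-form pairwise odds ratio recoverable by exact
  enumeration of the 2x2 cell probabilities;
* independent background genes;
* driver-conditional TMB: log-normal per histology, scaled by the
  driver's multiplier, truncated at 200 mutations/Mb (mirroring the
  cohort's ultra-hypermutated exclusion);
* driver-conditional PD-L1: a 3-level multinomial (negative/low/high),
  with the tumor proportion score drawn uniformly within the band.

Randomness is a single global seed feeding a counter-based (Philox)
stream per sample, so enlarging the gene list never perturbs the draws
of earlier samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_model import (
    AltClass,
    AlterationRecord,
    Component,
    Histology,
    MsiStatus,
    SampleRecord,
    Sex,
    SpecimenSite,
    Stage,
    Tier,
    RNA_ONLY_CLASSES,
    TMB_ULTRA_HYPERMUTATED,
)

__all__ = [
    "DriverSpec",
    "ModuleSpec",
    "SimConfig",
    "SimConfigError",
    "default_study_config",
    "generate_cohort",
    "implied_pair_or",
    "implied_gene_prevalence",
    "load_sim_config",
    "write_cohort",
]

ADENO = Histology.ADENOCARCINOMA.value
SQUAM = Histology.SQUAMOUS.value

# PD-L1 TPS bands the 3-level draw fills uniformly.
_PDL1_BANDS = {"negative": (0.0, 1.0), "low": (1.0, 50.0), "high": (50.0, 100.0)}


class SimConfigError(ValueError):
    """Raised for an infeasible or inconsistent simulation spec."""


def _per_hist(value) -> dict[str, float]:
    """Accept a scalar or an {adenocarcinoma, squamous} mapping."""
    if isinstance(value, Mapping):
        out = {ADENO: float(value[ADENO]), SQUAM: float(value[SQUAM])}
    else:
        out = {ADENO: float(value), SQUAM: float(value)}
    for v in out.values():
        if not 0.0 <= v <= 1.0:
            raise SimConfigError(f"probability out of [0,1]: {v}")
    return out


@dataclass(frozen=True)
class DriverSpec:
    """One mutually exclusive driver gene.

    ``prob`` is the per-histology probability that a tumor carries this
    driver; ``variants`` is the label mix, each entry
    (variant_label, alt_class, tier, weight); ``tmb_multiplier`` scales
    the histology's base TMB draw; ``pdl1_dist`` (negative, low, high)
    overrides the histology base PD-L1 level distribution when given.
    """

    gene: str
    prob: Mapping[str, float]
    variants: tuple[tuple[str, AltClass, Tier, float], ...] = (
        ("driver_mut", AltClass.SUBSTITUTION, Tier.GUIDELINE_INDICATED, 1.0),
    )
    tmb_multiplier: float = 1.0
    pdl1_dist: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-occurrence module (latent-Bernoulli mixture).

    With the latent state on (probability ``latent_prob`` per histology)
    each member gene is altered independently with its ``p_on``; off,
    with ``p_off``.  The induced pairwise odds ratio follows in closed
    form from the four mixture cell probabilities.
    """

    genes: tuple[str, ...]
    latent_prob: Mapping[str, float]
    p_on: Mapping[str, float]
    p_off: Mapping[str, float]
    # optional dose effects: TMB multiplied by this factor per altered
    # member gene; PD-L1 level distribution keyed by min(count, 2)
    tmb_multiplier_per_alt: float = 1.0
    pdl1_dist_by_count: Mapping[int, tuple[float, float, float]] | None = None

    def rates(self, gene: str) -> tuple[float, float]:
        return float(self.p_on[gene]), float(self.p_off[gene])


@dataclass
class SimConfig:
    n_samples: int
    frac_adeno: float = 0.726
    drivers: list[DriverSpec] = field(default_factory=list)
    modules: list[ModuleSpec] = field(default_factory=list)
    background: dict[str, Mapping[str, float]] = field(default_factory=dict)
    # log-normal TMB base per histology: (meanlog, sdlog) of mutations/Mb
    tmb_base: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {ADENO: (1.95, 1.0), SQUAM: (2.15, 0.85)}
    )
    # base PD-L1 level distribution per histology: (negative, low, high)
    pdl1_base: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            ADENO: (0.391, 0.351, 0.258),
            SQUAM: (0.323, 0.445, 0.232),
        }
    )
    tmb_missing_rate: float = 0.0
    pdl1_missing_rate: float = 0.0
    rna_fail_rate: float = 0.0
    dna_fail_rate: float = 0.0
    truncate_tmb: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise SimConfigError("n_samples must be positive")
        if not 0.0 <= self.frac_adeno <= 1.0:
            raise SimConfigError("frac_adeno must be a probability")
        seen: dict[str, str] = {}
        for d in self.drivers:
            if d.gene in seen:
                raise SimConfigError(f"gene {d.gene} in multiple specs")
            seen[d.gene] = "driver"
        for m in self.modules:
            for g in m.genes:
                if g in seen:
                    raise SimConfigError(f"gene {g} in multiple specs")
                seen[g] = "module"
        for g in self.background:
            if g in seen:
                raise SimConfigError(f"gene {g} in multiple specs")
            seen[g] = "background"
        for hist in (ADENO, SQUAM):
            total = sum(_per_hist(d.prob)[hist] for d in self.drivers)
            if total > 1.0 + 1e-12:
                raise SimConfigError(
                    f"driver probabilities sum to {total:.3f} > 1 for {hist}"
                )


def default_study_config(n_samples: int = 2000, seed: int = 0) -> SimConfig:
    """The canonical synthetic study: recovery surface for the full pipeline.

    Three mutually exclusive drivers at >=5% marginal prevalence — KRAS
    (neutral TMB), EGFR (TMB multiplier 0.5, the planted low-TMB
    driver), and BRAF (planted high-PD-L1 driver, high-level probability
    0.6 against a ~0.25 base) — plus three planted co-occurrence modules
    whose implied pairwise odds ratios all exceed 8 (a two-gene
    STK11/KEAP1-style module, a tight three-gene FGF-cluster-style
    module, and a looser three-gene module), and five independent
    background genes with histology-dependent rates.  Driver
    prevalences and histology/marker base rates echo a large clinical
    NSCLC profiling cohort.
    """
    drivers = [
        DriverSpec(
            gene="KRAS",
            prob={ADENO: 0.375, SQUAM: 0.046},
            variants=(
                ("G12C", AltClass.SUBSTITUTION, Tier.GUIDELINE_INDICATED, 0.4),
                ("G12V", AltClass.SUBSTITUTION, Tier.TRIAL_OR_OTHER_TUMOR, 0.3),
                ("G12D", AltClass.SUBSTITUTION, Tier.TRIAL_OR_OTHER_TUMOR, 0.3),
            ),
            tmb_multiplier=1.0,
        ),
        DriverSpec(
            gene="EGFR",
            prob={ADENO: 0.171, SQUAM: 0.013},
            variants=(
                ("L858R", AltClass.SUBSTITUTION, Tier.GUIDELINE_INDICATED, 0.6),
                ("E746_A750del", AltClass.INDEL, Tier.GUIDELINE_INDICATED, 0.4),
            ),
            tmb_multiplier=0.5,
            pdl1_dist=(0.45, 0.40, 0.15),
        ),
        DriverSpec(
            gene="BRAF",
            prob={ADENO: 0.07, SQUAM: 0.02},
            variants=(("V600E", AltClass.SUBSTITUTION,
                       Tier.GUIDELINE_INDICATED, 1.0),),
            tmb_multiplier=0.6,
            pdl1_dist=(0.15, 0.25, 0.60),
        ),
    ]
    modules = [
        ModuleSpec(
            genes=("STK11", "KEAP1"),
            latent_prob=0.15,
            p_on={"STK11": 0.65, "KEAP1": 0.65},
            p_off={"STK11": 0.02, "KEAP1": 0.02},
        ),
        ModuleSpec(
            genes=("FGF3", "FGF4", "CCND1"),
            latent_prob=0.06,
            p_on={g: 0.85 for g in ("FGF3", "FGF4", "CCND1")},
            p_off={g: 0.005 for g in ("FGF3", "FGF4", "CCND1")},
        ),
        ModuleSpec(
            genes=("ATRX", "GRIN2A", "LRP1B"),
            latent_prob=0.10,
            p_on={g: 0.55 for g in ("ATRX", "GRIN2A", "LRP1B")},
            p_off={g: 0.015 for g in ("ATRX", "GRIN2A", "LRP1B")},
        ),
    ]
    background = {
        "TP53": {ADENO: 0.49, SQUAM: 0.82},
        "CDKN2A": {ADENO: 0.044, SQUAM: 0.163},
        "PIK3CA": {ADENO: 0.042, SQUAM: 0.116},
        "RB1": {ADENO: 0.041, SQUAM: 0.066},
        "NF1": {ADENO: 0.08, SQUAM: 0.08},
    }
    return SimConfig(
        n_samples=n_samples,
        frac_adeno=0.726,
        drivers=drivers,
        modules=modules,
        background=background,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exact implied quantities (recovery targets)
# ---------------------------------------------------------------------------

def _module_cells(
    module: ModuleSpec, gene_i: str, gene_j: str, frac_adeno: float
) -> np.ndarray:
    """Exact 2x2 cell probabilities (p11, p10, p01, p00) for a module pair.

    Enumerates the latent-on/off mixture within each histology and mixes
    over the histology fractions.
    """
    if gene_i not in module.genes or gene_j not in module.genes:
        raise SimConfigError("genes must belong to the same planted module")
    latent = _per_hist(module.latent_prob)
    pi1, pi0 = module.rates(gene_i)
    pj1, pj0 = module.rates(gene_j)
    cells = np.zeros(4)
    for hist, w in ((ADENO, frac_adeno), (SQUAM, 1.0 - frac_adeno)):
        lam = latent[hist]
        for state, ws in ((1, lam), (0, 1.0 - lam)):
            pi = pi1 if state else pi0
            pj = pj1 if state else pj0
            cells += w * ws * np.array(
                [pi * pj, pi * (1 - pj), (1 - pi) * pj, (1 - pi) * (1 - pj)]
            )
    return cells


def implied_pair_or(
    module: ModuleSpec, gene_i: str, gene_j: str, frac_adeno: float = 0.726
) -> float:
    """Exact pairwise odds ratio implied by the planted mixture."""
    p11, p10, p01, p00 = _module_cells(module, gene_i, gene_j, frac_adeno)
    if p10 == 0.0 or p01 == 0.0:
        return float("inf")
    return float(p11 * p00 / (p10 * p01))


def implied_gene_prevalence(config: SimConfig, gene: str) -> float:
    """Exact marginal alteration probability of ``gene`` under the config."""
    w = {ADENO: config.frac_adeno, SQUAM: 1.0 - config.frac_adeno}
    for d in config.drivers:
        if d.gene == gene:
            p = _per_hist(d.prob)
            return sum(w[h] * p[h] for h in w)
    for m in config.modules:
        if gene in m.genes:
            lam = _per_hist(m.latent_prob)
            p1, p0 = m.rates(gene)
            return sum(w[h] * (lam[h] * p1 + (1 - lam[h]) * p0) for h in w)
    if gene in config.background:
        p = _per_hist(config.background[gene])
        return sum(w[h] * p[h] for h in w)
    raise SimConfigError(f"gene {gene} not in config")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based per-sample stream: one Philox key, sample index as counter."""
    return np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, index]))


def _variant_component(alt_class: AltClass) -> Component:
    return Component.RNA if alt_class in RNA_ONLY_CLASSES else Component.DNA


def generate_cohort(
    config: SimConfig,
) -> tuple[list[SampleRecord], list[AlterationRecord], dict]:
    """Generate a cohort; deterministic given ``config.seed``.

    Returns samples, alterations, and a truth record holding every
    planted parameter together with the implied exact per-gene
    prevalences and module pairwise odds ratios (the recovery targets).
    """
    config.validate()
    samples: list[SampleRecord] = []
    alterations: list[AlterationRecord] = []
    driver_probs = [_per_hist(d.prob) for d in config.drivers]

    for i in range(config.n_samples):
        rng = _sample_rng(config.seed, i)
        sid = f"S{i:05d}"
        hist = ADENO if rng.random() < config.frac_adeno else SQUAM
        dna_pass = rng.random() >= config.dna_fail_rate
        rna_pass = rng.random() >= config.rna_fail_rate

        # --- driver: categorical, at most one per sample (exclusivity) ---
        u = rng.random()
        driver: DriverSpec | None = None
        acc = 0.0
        for d, p in zip(config.drivers, driver_probs):
            acc += p[hist]
            if u < acc:
                driver = d
                break
        altered_genes: list[tuple[str, str, AltClass, Tier]] = []
        if driver is not None:
            weights = np.array([v[3] for v in driver.variants], dtype=float)
            k = int(rng.choice(len(driver.variants), p=weights / weights.sum()))
            label, alt_class, tier, _ = driver.variants[k]
            altered_genes.append((driver.gene, label, alt_class, tier))

        # --- planted modules: latent-Bernoulli mixture ---
        module_counts: list[int] = []
        for m in config.modules:
            lam = _per_hist(m.latent_prob)[hist]
            on = rng.random() < lam
            count = 0
            for g in m.genes:
                p1, p0 = m.rates(g)
                if rng.random() < (p1 if on else p0):
                    count += 1
                    altered_genes.append(
                        (g, "module_mut", AltClass.SUBSTITUTION,
                         Tier.PATHOGENIC_UNKNOWN)
                    )
            module_counts.append(count)

        # --- independent background genes ---
        for g in sorted(config.background):
            p = _per_hist(config.background[g])[hist]
            if rng.random() < p:
                altered_genes.append(
                    (g, "bg_mut", AltClass.SUBSTITUTION, Tier.PATHOGENIC_UNKNOWN)
                )

        # --- TMB: log-normal base x driver multiplier, truncated ---
        meanlog, sdlog = config.tmb_base[hist]
        tmb = float(rng.lognormal(meanlog, sdlog))
        if driver is not None:
            tmb *= driver.tmb_multiplier
        for m, count in zip(config.modules, module_counts):
            tmb *= m.tmb_multiplier_per_alt ** count
        if config.truncate_tmb:
            tmb = min(tmb, TMB_ULTRA_HYPERMUTATED)
        if rng.random() < config.tmb_missing_rate:
            tmb_out: float | None = None
        else:
            tmb_out = tmb

        # --- PD-L1: 3-level draw, TPS uniform within band ---
        if driver is not None and driver.pdl1_dist is not None:
            levels = driver.pdl1_dist
        else:
            levels = config.pdl1_base[hist]
            for m, count in zip(config.modules, module_counts):
                if m.pdl1_dist_by_count is not None:
                    levels = m.pdl1_dist_by_count[min(count, 2)]
                    break
        lv = int(rng.choice(3, p=np.asarray(levels) / np.sum(levels)))
        lo, hi = _PDL1_BANDS[("negative", "low", "high")[lv]]
        tps = float(rng.uniform(lo, hi))
        if rng.random() < config.pdl1_missing_rate:
            tps_out: float | None = None
        else:
            tps_out = tps

        age = float(np.clip(rng.normal(70.7, 9.7), 18.0, 100.0))
        sex = Sex.FEMALE if rng.random() < 0.51 else Sex.MALE

        samples.append(
            SampleRecord(
                sample_id=sid,
                histology=Histology(hist),
                sex=sex,
                age=round(age, 1),
                stage=Stage.UNKNOWN,
                specimen_site=SpecimenSite.PRIMARY,
                tmb=None if tmb_out is None else round(tmb_out, 2),
                pdl1_tps=None if tps_out is None else round(tps_out, 1),
                msi=MsiStatus.STABLE,
                dna_pass=dna_pass,
                rna_pass=rna_pass,
            )
        )
        for g, label, alt_class, tier in altered_genes:
            comp = _variant_component(alt_class)
            if comp is Component.DNA and not dna_pass:
                continue
            if comp is Component.RNA and not rna_pass:
                continue
            alterations.append(
                AlterationRecord(sid, g, label, alt_class, comp, tier)
            )

    truth = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "frac_adeno": config.frac_adeno,
        "drivers": [
            {
                "gene": d.gene,
                "prob": _per_hist(d.prob),
                "tmb_multiplier": d.tmb_multiplier,
                "pdl1_dist": None if d.pdl1_dist is None else list(d.pdl1_dist),
                "implied_prevalence": implied_gene_prevalence(config, d.gene),
            }
            for d in config.drivers
        ],
        "modules": [
            {
                "genes": list(m.genes),
                "latent_prob": _per_hist(m.latent_prob),
                "p_on": {g: m.rates(g)[0] for g in m.genes},
                "p_off": {g: m.rates(g)[1] for g in m.genes},
                "implied_prevalence": {
                    g: implied_gene_prevalence(config, g) for g in m.genes
                },
                "implied_pair_or": {
                    f"{a}|{b}": implied_pair_or(m, a, b, config.frac_adeno)
                    for ai, a in enumerate(m.genes)
                    for b in m.genes[ai + 1:]
                },
            }
            for m in config.modules
        ],
        "background": {
            g: implied_gene_prevalence(config, g) for g in config.background
        },
        "module_partition": {
            g: idx for idx, m in enumerate(config.modules) for g in m.genes
        },
    }
    return samples, alterations, truth


# ---------------------------------------------------------------------------
# YAML config + output
# ---------------------------------------------------------------------------

def load_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from YAML (schema mirrors the dataclasses)."""
    with Path(path).open(encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    drivers = [
        DriverSpec(
            gene=d["gene"],
            prob=d["prob"],
            variants=tuple(
                (
                    v.get("label", "driver_mut"),
                    AltClass.parse(v.get("alt_class", "substitution")),
                    Tier.parse(v.get("tier", "guideline_indicated")),
                    float(v.get("weight", 1.0)),
                )
                for v in d.get("variants", [{}])
            ),
            tmb_multiplier=float(d.get("tmb_multiplier", 1.0)),
            pdl1_dist=tuple(d["pdl1_dist"]) if d.get("pdl1_dist") else None,
        )
        for d in raw.get("drivers", [])
    ]
    modules = [
        ModuleSpec(
            genes=tuple(m["genes"]),
            latent_prob=m["latent_prob"],
            p_on={g: float(m["p_on"][g]) if isinstance(m["p_on"], Mapping)
                  else float(m["p_on"]) for g in m["genes"]},
            p_off={g: float(m["p_off"][g]) if isinstance(m["p_off"], Mapping)
                   else float(m["p_off"]) for g in m["genes"]},
        )
        for m in raw.get("modules", [])
    ]
    kwargs = {
        k: raw[k]
        for k in (
            "frac_adeno",
            "tmb_missing_rate",
            "pdl1_missing_rate",
            "rna_fail_rate",
            "dna_fail_rate",
            "truncate_tmb",
            "seed",
        )
        if k in raw
    }
    if "tmb_base" in raw:
        kwargs["tmb_base"] = {h: tuple(v) for h, v in raw["tmb_base"].items()}
    if "pdl1_base" in raw:
        kwargs["pdl1_base"] = {h: tuple(v) for h, v in raw["pdl1_base"].items()}
    return SimConfig(
        n_samples=int(raw["n_samples"]),
        drivers=drivers,
        modules=modules,
        background=dict(raw.get("background", {})),
        **kwargs,
    )


def write_cohort(
    samples: Sequence[SampleRecord],
    alterations: Sequence[AlterationRecord],
    truth: dict,
    out_dir: str | Path,
) -> None:
    from .io_model import write_alterations, write_samples

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_samples(samples, out / "samples.tsv")
    write_alterations(alterations, out / "alterations.tsv")
    with (out / "truth.json").open("w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=2, default=float)
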