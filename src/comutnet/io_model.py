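"""Domain types, readers, cohort filters, and immunotherapy-marker binning.

The pipeline operates on two flat tables: one row per tumor sample
(histology, demographics, TMB in mutations/Mb, PD-L1 tumor proportion
score, MSI, per-assay-component QC flags) and one row per detected
pathogenic alteration (gene, variant label, alteration class, detection
component, clinical tier).  Everything downstream — prevalence,
driver/immune association tests, co-occurrence networks, dose–response —
consumes the filtered cohort or the boolean gene-by-sample matrix built
here.

File dialect: TSV, UTF-8, header required; empty string or ``NA`` means
missing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Histology",
    "Sex",
    "Stage",
    "SpecimenSite",
    "MsiStatus",
    "AltClass",
    "Component",
    "Tier",
    "Pdl1Level",
    "TmbLevel",
    "SampleRecord",
    "AlterationRecord",
    "GeneAlterationMatrix",
    "MarkerLevels",
    "CohortError",
    "Exclusion",
    "TMB_ULTRA_HYPERMUTATED",
    "DEFAULT_RNA_GENES",
    "read_samples",
    "read_alterations",
    "write_samples",
    "write_alterations",
    "write_exclusions_log",
    "apply_cohort_filters",
    "build_gene_matrix",
    "gene_components",
    "load_registry_config",
    "bin_markers",
    "pdl1_level",
    "tmb_level",
    "round_half_up",
]

# Cohort filter: tumors above this TMB are ultra-hypermutated and excluded.
TMB_ULTRA_HYPERMUTATED = 200.0

# PD-L1 TPS category boundaries (percent of tumor cells staining).
PDL1_POSITIVE_CUT = 1.0
PDL1_HIGH_CUT = 50.0

# TMB category boundaries (mutations/Mb); printed bands "<10", "10-19",
# ">=20" are read as the partition [0,10), [10,20), [20, inf).
TMB_HIGH_CUT = 10.0
TMB_VERY_HIGH_CUT = 20.0


class CohortError(ValueError):
    """Raised when an input table violates the cohort schema."""


class _NormEnum(str, Enum):
    """String enum with case-insensitive, synonym-aware parsing."""

    @classmethod
    def _synonyms(cls) -> Mapping[str, str]:
        return {}

    @classmethod
    def parse(cls, raw: str):
        key = raw.strip().lower()
        key = cls._synonyms().get(key, key)
        for member in cls:
            if member.value == key:
                return member
        raise CohortError(f"{cls.__name__}: unknown value {raw!r}")


class Histology(_NormEnum):
    ADENOCARCINOMA = "adenocarcinoma"
    SQUAMOUS = "squamous"
    OTHER = "other"

    @classmethod
    def _synonyms(cls):
        return {
            "adeno": "adenocarcinoma",
            "lung adenocarcinoma": "adenocarcinoma",
            "squamous cell carcinoma": "squamous",
            "scc": "squamous",
        }


class Sex(_NormEnum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"

    @classmethod
    def _synonyms(cls):
        return {"f": "female", "m": "male", "": "unknown"}


class Stage(_NormEnum):
    I = "i"
    II = "ii"
    III = "iii"
    IV = "iv"
    UNKNOWN = "unknown"

    @classmethod
    def _synonyms(cls):
        return {"1": "i", "2": "ii", "3": "iii", "4": "iv", "": "unknown"}


class SpecimenSite(_NormEnum):
    PRIMARY = "primary"
    ADVANCED = "advanced"
    METASTATIC = "metastatic"
    UNKNOWN = "unknown"

    @classmethod
    def _synonyms(cls):
        return {"met": "metastatic", "": "unknown"}


class MsiStatus(_NormEnum):
    HIGH = "high"
    STABLE = "stable"
    MISSING = "missing"

    @classmethod
    def _synonyms(cls):
        return {"msi-high": "high", "msi-h": "high", "mss": "stable", "": "missing"}


class AltClass(_NormEnum):
    SUBSTITUTION = "substitution"
    INDEL = "indel"
    SPLICE = "splice"
    COMPLEX_SNV = "complex_snv"
    CNV_GAIN = "cnv_gain"
    CNV_LOSS = "cnv_loss"
    FUSION = "fusion"
    EXON_SKIP = "exon_skip"

    @classmethod
    def _synonyms(cls):
        return {
            "snv": "substitution",
            "amplification": "cnv_gain",
            "deletion_cnv": "cnv_loss",
            "exon skipping": "exon_skip",
        }


class Component(_NormEnum):
    DNA = "dna"
    RNA = "rna"


class Tier(_NormEnum):
    GUIDELINE_INDICATED = "guideline_indicated"
    TRIAL_OR_OTHER_TUMOR = "trial_or_other_tumor"
    PATHOGENIC_UNKNOWN = "pathogenic_unknown"


class Pdl1Level(_NormEnum):
    NEGATIVE = "negative"  # TPS < 1
    LOW = "low"            # 1 <= TPS < 50
    HIGH = "high"          # TPS >= 50


class TmbLevel(_NormEnum):
    NOT_HIGH = "not_high"    # TMB < 10
    HIGH = "high"            # 10 <= TMB < 20
    VERY_HIGH = "very_high"  # TMB >= 20


# Alteration classes only callable from the RNA component of the assay.
RNA_ONLY_CLASSES = {AltClass.FUSION, AltClass.EXON_SKIP}

# Genes whose pathogenic spectrum includes RNA-detected events
# (fusions / exon skipping) and therefore require both assay components.
DEFAULT_RNA_GENES = frozenset(
    {
        "ALK",
        "ROS1",
        "RET",
        "MET",
        "NTRK1",
        "NTRK2",
        "NTRK3",
        "FGFR1",
        "FGFR2",
        "FGFR3",
    }
)


@dataclass(frozen=True)
class SampleRecord:
    """One tumor's clinical and immunotherapy-marker variables."""

    sample_id: str
    histology: Histology
    sex: Sex = Sex.UNKNOWN
    age: float | None = None
    stage: Stage = Stage.UNKNOWN
    specimen_site: SpecimenSite = SpecimenSite.UNKNOWN
    tmb: float | None = None
    pdl1_tps: float | None = None
    msi: MsiStatus = MsiStatus.MISSING
    dna_pass: bool = True
    rna_pass: bool = True


@dataclass(frozen=True)
class AlterationRecord:
    """One known-pathogenic alteration call."""

    sample_id: str
    gene: str
    variant_label: str
    alt_class: AltClass
    component: Component
    tier: Tier = Tier.PATHOGENIC_UNKNOWN


@dataclass(frozen=True)
class MarkerLevels:
    """Categorical immunotherapy-marker levels for one sample."""

    pdl1_level: Pdl1Level | None
    tmb_level: TmbLevel | None


@dataclass(frozen=True)
class Exclusion:
    sample_id: str
    reason: str


@dataclass
class GeneAlterationMatrix:
    """Boolean samples x genes presence matrix with an assayability mask.

    ``altered[s, g]`` is true iff sample ``s`` has at least one pathogenic
    alteration in gene ``g``.  ``assayable[s, g]`` is true iff the sample
    passed every assay component required to call the gene's full
    alteration spectrum; ``altered`` implies ``assayable``.
    """

    samples: list[str]
    genes: list[str]
    altered: np.ndarray
    assayable: np.ndarray
    _gene_index: dict[str, int] = field(init=False, repr=False)
    _sample_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ns, ng = len(self.samples), len(self.genes)
        if self.altered.shape != (ns, ng) or self.assayable.shape != (ns, ng):
            raise CohortError("matrix dimensions inconsistent with id lists")
        if np.any(self.altered & ~self.assayable):
            raise CohortError("altered cell in non-assayable sample/gene")
        self.altered = np.asarray(self.altered, dtype=bool)
        self.assayable = np.asarray(self.assayable, dtype=bool)
        self._gene_index = {g: j for j, g in enumerate(self.genes)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def gene_column(self, gene: str) -> np.ndarray:
        return self.altered[:, self._gene_index[gene]]

    def gene_assayable(self, gene: str) -> np.ndarray:
        return self.assayable[:, self._gene_index[gene]]

    def prevalence(self, gene: str) -> float:
        """Percent of assayable samples altered in ``gene``."""
        j = self._gene_index[gene]
        denom = int(self.assayable[:, j].sum())
        if denom == 0:
            return 0.0
        return 100.0 * float(self.altered[:, j].sum()) / denom


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_MISSING = {"", "na", "nan", "none", "."}


def _is_missing(raw: str | None) -> bool:
    return raw is None or raw.strip().lower() in _MISSING


def _parse_float(raw: str, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise CohortError(f"row {row}: column {col!r}: not a number: {raw!r}") from exc


def _parse_bool(raw: str, row: int, col: str) -> bool:
    key = raw.strip().lower()
    if key in {"true", "t", "1", "yes", "pass"}:
        return True
    if key in {"false", "f", "0", "no", "fail"}:
        return False
    raise CohortError(f"row {row}: column {col!r}: not a boolean: {raw!r}")


SAMPLE_COLUMNS = [
    "sample_id",
    "histology",
    "sex",
    "age",
    "stage",
    "specimen_site",
    "tmb",
    "pdl1_tps",
    "msi",
    "dna_pass",
    "rna_pass",
]

ALTERATION_COLUMNS = [
    "sample_id",
    "gene",
    "variant_label",
    "alt_class",
    "component",
    "tier",
]


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read the sample-metadata TSV, validating every row.

    Raises :class:`CohortError` on a missing required column, duplicate
    sample ids, or a PD-L1 TPS outside [0, 100]; the error names the
    offending row.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in header]
        if missing_cols:
            raise CohortError(f"{path}: missing required columns {missing_cols}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            sid = (row["sample_id"] or "").strip()
            if not sid:
                raise CohortError(f"row {i}: empty sample_id")
            if sid in seen:
                raise CohortError(f"row {i}: duplicate sample_id {sid!r}")
            seen.add(sid)
            age = None if _is_missing(row["age"]) else _parse_float(row["age"], i, "age")
            if age is not None and age < 0:
                raise CohortError(f"row {i}: negative age for {sid!r}")
            tmb = None if _is_missing(row["tmb"]) else _parse_float(row["tmb"], i, "tmb")
            if tmb is not None and tmb < 0:
                raise CohortError(f"row {i}: negative TMB for {sid!r}")
            tps = (
                None
                if _is_missing(row["pdl1_tps"])
                else _parse_float(row["pdl1_tps"], i, "pdl1_tps")
            )
            if tps is not None and not 0.0 <= tps <= 100.0:
                raise CohortError(f"row {i}: PD-L1 TPS out of [0,100] for {sid!r}: {tps}")
            records.append(
                SampleRecord(
                    sample_id=sid,
                    histology=Histology.parse(row["histology"]),
                    sex=Sex.parse(row["sex"] or ""),
                    age=age,
                    stage=Stage.parse(row["stage"] or ""),
                    specimen_site=SpecimenSite.parse(row["specimen_site"] or ""),
                    tmb=tmb,
                    pdl1_tps=tps,
                    msi=MsiStatus.parse(row["msi"] or ""),
                    dna_pass=_parse_bool(row["dna_pass"], i, "dna_pass"),
                    rna_pass=_parse_bool(row["rna_pass"], i, "rna_pass"),
                )
            )
    return records


def read_alterations(
    path: str | Path,
    samples: Sequence[SampleRecord] | None = None,
) -> list[AlterationRecord]:
    """Read the alteration TSV; validate against the sample table if given."""
    path = Path(path)
    known_ids = {s.sample_id for s in samples} if samples is not None else None
    records: list[AlterationRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        missing_cols = [c for c in ALTERATION_COLUMNS if c not in header]
        if missing_cols:
            raise CohortError(f"{path}: missing required columns {missing_cols}")
        for i, row in enumerate(reader, start=2):
            sid = (row["sample_id"] or "").strip()
            if known_ids is not None and sid not in known_ids:
                raise CohortError(f"row {i}: unknown sample_id {sid!r}")
            rec = AlterationRecord(
                sample_id=sid,
                gene=(row["gene"] or "").strip(),
                variant_label=(row["variant_label"] or "").strip(),
                alt_class=AltClass.parse(row["alt_class"]),
                component=Component.parse(row["component"]),
                tier=Tier.parse(row["tier"]),
            )
            if rec.alt_class in RNA_ONLY_CLASSES and rec.component is not Component.RNA:
                raise CohortError(
                    f"row {i}: {rec.alt_class.value} record for {rec.gene} "
                    f"must have component=RNA"
                )
            if not rec.gene:
                raise CohortError(f"row {i}: empty gene symbol")
            records.append(rec)
    return records


def write_samples(samples: Iterable[SampleRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SAMPLE_COLUMNS)
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.histology.value,
                    s.sex.value,
                    "" if s.age is None else f"{s.age:g}",
                    s.stage.value,
                    s.specimen_site.value,
                    "" if s.tmb is None else f"{s.tmb:g}",
                    "" if s.pdl1_tps is None else f"{s.pdl1_tps:g}",
                    s.msi.value,
                    str(s.dna_pass).lower(),
                    str(s.rna_pass).lower(),
                ]
            )


def write_alterations(alterations: Iterable[AlterationRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ALTERATION_COLUMNS)
        for a in alterations:
            writer.writerow(
                [a.sample_id, a.gene, a.variant_label, a.alt_class.value,
                 a.component.value, a.tier.value]
            )


def write_exclusions_log(exclusions: Iterable[Exclusion], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for e in exclusions:
            handle.write(f"{e.sample_id}\t{e.reason}\n")


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

def apply_cohort_filters(
    samples: Sequence[SampleRecord],
    alterations: Sequence[AlterationRecord],
) -> tuple[list[SampleRecord], list[AlterationRecord], list[Exclusion]]:
    """Apply the study's cohort inclusion rules.

    Ultra-hypermutated tumors (TMB strictly above 200 mutations/Mb) and
    tumors whose histology is neither adenocarcinoma nor squamous cell
    carcinoma are excluded, together with their alterations.  Returns the
    retained samples and alterations plus an exclusion log.  Idempotent.
    """
    kept: list[SampleRecord] = []
    exclusions: list[Exclusion] = []
    for s in samples:
        if s.tmb is not None and s.tmb > TMB_ULTRA_HYPERMUTATED:
            exclusions.append(Exclusion(s.sample_id, "ultra-hypermutated"))
        elif s.histology not in (Histology.ADENOCARCINOMA, Histology.SQUAMOUS):
            exclusions.append(Exclusion(s.sample_id, "non-adeno/squamous histology"))
        else:
            kept.append(s)
    kept_ids = {s.sample_id for s in kept}
    kept_alts = [a for a in alterations if a.sample_id in kept_ids]
    return kept, kept_alts, exclusions


# ---------------------------------------------------------------------------
# gene matrix
# ---------------------------------------------------------------------------

def gene_components(
    gene: str, registry: Mapping[str, Sequence[str]] | None = None
) -> frozenset[Component]:
    """Assay components required to call ``gene``'s full alteration spectrum.

    ``registry`` maps gene symbol to a list of component names; a gene
    absent from the registry is treated as DNA-only.
    """
    if registry is not None:
        if gene in registry:
            return frozenset(Component.parse(c) for c in registry[gene])
        return frozenset({Component.DNA})
    if gene in DEFAULT_RNA_GENES:
        return frozenset({Component.DNA, Component.RNA})
    return frozenset({Component.DNA})


def load_registry_config(path: str | Path) -> dict[str, list[str]]:
    """Load a YAML gene -> required-components registry."""
    with Path(path).open(encoding="utf-8") as handle:
        cfg = yaml.safe_load(handle) or {}
    registry = cfg.get("gene_components", cfg)
    return {str(g): [str(c) for c in comps] for g, comps in registry.items()}


def build_gene_matrix(
    samples: Sequence[SampleRecord],
    alterations: Sequence[AlterationRecord],
    registry: Mapping[str, Sequence[str]] | None = None,
    genes: Sequence[str] | None = None,
) -> GeneAlterationMatrix:
    """Summarize alterations at the gene level into a boolean matrix.

    A cell is altered iff the sample has >=1 alteration record for the
    gene; it is assayable iff the sample passed every assay component
    the gene requires (mixed-spectrum genes such as MET require both DNA
    and RNA).  An altered cell in a non-assayable sample raises, since a
    call cannot come from a failed component.
    """
    sample_ids = [s.sample_id for s in samples]
    if genes is None:
        genes = sorted({a.gene for a in alterations})
    else:
        genes = list(genes)
    sidx = {sid: i for i, sid in enumerate(sample_ids)}
    gidx = {g: j for j, g in enumerate(genes)}
    altered = np.zeros((len(sample_ids), len(genes)), dtype=bool)
    for a in alterations:
        if a.sample_id in sidx and a.gene in gidx:
            altered[sidx[a.sample_id], gidx[a.gene]] = True
    dna_pass = np.array([s.dna_pass for s in samples], dtype=bool)
    rna_pass = np.array([s.rna_pass for s in samples], dtype=bool)
    assayable = np.ones_like(altered)
    for j, g in enumerate(genes):
        comps = gene_components(g, registry)
        col = np.ones(len(sample_ids), dtype=bool)
        if Component.DNA in comps:
            col &= dna_pass
        if Component.RNA in comps:
            col &= rna_pass
        assayable[:, j] = col
    # A call recorded against a failed component cannot be trusted either
    # way; the cell is treated as not-assayed rather than altered.
    inconsistent = altered & ~assayable
    if inconsistent.any():
        warnings.warn(
            f"{int(inconsistent.sum())} alteration call(s) in samples failing "
            "a required assay component; masked as not-assayed",
            stacklevel=2,
        )
        altered &= assayable
    return GeneAlterationMatrix(sample_ids, genes, altered, assayable)


# ---------------------------------------------------------------------------
# marker binning
# ---------------------------------------------------------------------------

def pdl1_level(tps: float | None) -> Pdl1Level | None:
    """Map a PD-L1 tumor proportion score to negative/low/high.

    Negative: TPS < 1; low: 1 <= TPS < 50; high: TPS >= 50.  The bands
    partition [0, 100], so a fractional score such as 49.5 is low.
    """
    if tps is None:
        return None
    if tps < PDL1_POSITIVE_CUT:
        return Pdl1Level.NEGATIVE
    if tps < PDL1_HIGH_CUT:
        return Pdl1Level.LOW
    return Pdl1Level.HIGH


def tmb_level(tmb: float | None) -> TmbLevel | None:
    """Map TMB (mutations/Mb) to not-high / high / very-high.

    Not-high: TMB < 10; high: 10 <= TMB < 20; very-high: TMB >= 20.
    Fractional values in (19, 20) fall in the high band so that the
    three bands partition the nonnegative reals.
    """
    if tmb is None:
        return None
    if tmb < TMB_HIGH_CUT:
        return TmbLevel.NOT_HIGH
    if tmb < TMB_VERY_HIGH_CUT:
        return TmbLevel.HIGH
    return TmbLevel.VERY_HIGH


def bin_markers(sample: SampleRecord) -> MarkerLevels:
    """Categorical PD-L1 / TMB levels for one sample (missing stays missing)."""
    return MarkerLevels(pdl1_level(sample.pdl1_tps), tmb_level(sample.tmb))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as clinical tables are printed."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
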