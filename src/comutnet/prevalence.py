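"""Gene- and variant-level alteration prevalence with assay-aware denominators.

Prevalence is the percent of tumors altered among tumors that passed the
assay component(s) in which the unit is detectable: DNA-only genes are
counted against DNA-pass samples, fusion/exon-skip events against
RNA-pass samples, and genes whose pathogenic spectrum spans both
components (e.g. MET: DNA substitutions plus RNA exon skipping) against
samples passing both — a tumor failing RNA cannot be called negative for
such a gene's full spectrum.  Histology enrichment is a two-sided
Fisher's exact test of altered vs not by adenocarcinoma vs squamous,
reported unadjusted with an optional BH column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import (
    AltClass,
    AlterationRecord,
    Histology,
    GeneAlterationMatrix,
    SampleRecord,
    RNA_ONLY_CLASSES,
    Component,
    gene_components,
)
from .network import bh_adjust

__all__ = ["PrevalenceRow", "alteration_prevalence", "variant_prevalence",
           "histology_enrichment", "write_prevalence_tsv"]


@dataclass
class PrevalenceRow:
    """Prevalence of one unit (a gene, or a specific variant within a gene)."""

    gene: str
    variant_label: str | None
    alt_class: str | None
    n_altered: int
    denominator: int
    prevalence: float  # percent
    n_adeno: int = 0
    denom_adeno: int = 0
    n_squam: int = 0
    denom_squam: int = 0
    p_histology: float | None = None
    q_histology: float | None = None
    enriched_in: str | None = None

    @property
    def prevalence_adeno(self) -> float:
        return 100.0 * self.n_adeno / self.denom_adeno if self.denom_adeno else 0.0

    @property
    def prevalence_squam(self) -> float:
        return 100.0 * self.n_squam / self.denom_squam if self.denom_squam else 0.0


def _split_by_histology(
    samples: Sequence[SampleRecord],
) -> tuple[np.ndarray, np.ndarray]:
    adeno = np.array([s.histology is Histology.ADENOCARCINOMA for s in samples])
    squam = np.array([s.histology is Histology.SQUAMOUS for s in samples])
    return adeno, squam


def alteration_prevalence(
    matrix: GeneAlterationMatrix,
    samples: Sequence[SampleRecord],
    min_prevalence: float = 0.1,
) -> list[PrevalenceRow]:
    """One row per gene with prevalence >= ``min_prevalence`` percent.

    The denominator is the number of samples assayable for the gene.
    Rows are sorted by descending prevalence (gene name breaks ties).
    """
    adeno, squam = _split_by_histology(samples)
    rows: list[PrevalenceRow] = []
    for g in matrix.genes:
        ok = matrix.gene_assayable(g)
        alt = matrix.gene_column(g)
        denom = int(ok.sum())
        if denom == 0:
            continue
        n = int(alt.sum())
        prev = 100.0 * n / denom
        if prev < min_prevalence:
            continue
        rows.append(
            PrevalenceRow(
                gene=g,
                variant_label=None,
                alt_class=None,
                n_altered=n,
                denominator=denom,
                prevalence=prev,
                n_adeno=int(np.sum(alt & adeno)),
                denom_adeno=int(np.sum(ok & adeno)),
                n_squam=int(np.sum(alt & squam)),
                denom_squam=int(np.sum(ok & squam)),
            )
        )
    rows.sort(key=lambda r: (-r.prevalence, r.gene))
    return rows


def variant_prevalence(
    alterations: Sequence[AlterationRecord],
    samples: Sequence[SampleRecord],
    min_prevalence: float = 0.1,
    registry: Mapping[str, Sequence[str]] | None = None,
) -> list[PrevalenceRow]:
    """Prevalence per (gene, variant label, alteration class).

    A variant recorded more than once for a sample counts once.  The
    denominator is the samples passing the variant's own detection
    component (RNA for fusions / exon skips, DNA otherwise), intersected
    with the gene's registry components when stricter.
    """
    adeno, squam = _split_by_histology(samples)
    dna_pass = np.array([s.dna_pass for s in samples])
    rna_pass = np.array([s.rna_pass for s in samples])
    sidx = {s.sample_id: i for i, s in enumerate(samples)}
    carriers: dict[tuple[str, str, str], set[int]] = {}
    for a in alterations:
        if a.sample_id not in sidx:
            continue
        key = (a.gene, a.variant_label, a.alt_class.value)
        carriers.setdefault(key, set()).add(sidx[a.sample_id])
    rows: list[PrevalenceRow] = []
    for (gene, label, klass), idxs in carriers.items():
        rna_unit = AltClass(klass) in RNA_ONLY_CLASSES
        ok = rna_pass.copy() if rna_unit else dna_pass.copy()
        if registry is not None and gene in registry:
            comps = gene_components(gene, registry)
            if Component.DNA in comps:
                ok &= dna_pass
            if Component.RNA in comps:
                ok &= rna_pass
        denom = int(ok.sum())
        if denom == 0:
            continue
        flag = np.zeros(len(samples), dtype=bool)
        flag[sorted(idxs)] = True
        flag &= ok
        n = int(flag.sum())
        prev = 100.0 * n / denom
        if prev < min_prevalence:
            continue
        rows.append(
            PrevalenceRow(
                gene=gene,
                variant_label=label,
                alt_class=klass,
                n_altered=n,
                denominator=denom,
                prevalence=prev,
                n_adeno=int(np.sum(flag & adeno)),
                denom_adeno=int(np.sum(ok & adeno)),
                n_squam=int(np.sum(flag & squam)),
                denom_squam=int(np.sum(ok & squam)),
            )
        )
    rows.sort(key=lambda r: (-r.prevalence, r.gene, r.variant_label or ""))
    return rows


def histology_enrichment(rows: Sequence[PrevalenceRow]) -> list[PrevalenceRow]:
    """Attach a two-sided Fisher p (and BH q) per unit, with direction flag.

    The table is altered vs not x adenocarcinoma vs squamous on the
    unit's own denominators; ``enriched_in`` names the histology with
    the higher prevalence when the proportions differ.
    """
    ps = []
    for r in rows:
        table = [
            [r.n_adeno, r.denom_adeno - r.n_adeno],
            [r.n_squam, r.denom_squam - r.n_squam],
        ]
        if r.denom_adeno == 0 or r.denom_squam == 0:
            r.p_histology = 1.0
        else:
            r.p_histology = float(stats.fisher_exact(table)[1])
        if r.prevalence_adeno > r.prevalence_squam:
            r.enriched_in = "adenocarcinoma"
        elif r.prevalence_squam > r.prevalence_adeno:
            r.enriched_in = "squamous"
        else:
            r.enriched_in = None
        ps.append(r.p_histology)
    if ps:
        for r, q in zip(rows, bh_adjust(ps)):
            r.q_histology = float(q)
    return list(rows)


def write_prevalence_tsv(rows: Sequence[PrevalenceRow], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "gene\tvariant_label\talt_class\tn_altered\tdenominator\tprevalence\t"
            "prevalence_adeno\tprevalence_squam\tp_histology\tq_histology\t"
            "enriched_in\n"
        )
        for r in rows:
            handle.write(
                f"{r.gene}\t{r.variant_label or ''}\t{r.alt_class or ''}\t"
                f"{r.n_altered}\t{r.denominator}\t{r.prevalence:.4f}\t"
                f"{r.prevalence_adeno:.4f}\t{r.prevalence_squam:.4f}\t"
                f"{'' if r.p_histology is None else f'{r.p_histology:.4g}'}\t"
                f"{'' if r.q_histology is None else f'{r.q_histology:.4g}'}\t"
                f"{r.enriched_in or ''}\n"
            )
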