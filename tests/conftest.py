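from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from comutnet import (
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
    build_gene_matrix,
)
from comutnet.synthetic import default_study_config, generate_cohort


def make_sample(sid, hist="adenocarcinoma", **kw):
    defaults = dict(
        sex=Sex.FEMALE,
        age=65.0,
        stage=Stage.IV,
        specimen_site=SpecimenSite.PRIMARY,
        tmb=8.0,
        pdl1_tps=10.0,
        msi=MsiStatus.STABLE,
        dna_pass=True,
        rna_pass=True,
    )
    defaults.update(kw)
    return SampleRecord(sample_id=sid, histology=Histology(hist), **defaults)


def make_alt(sid, gene, label="mut", alt_class=AltClass.SUBSTITUTION,
             component=Component.DNA, tier=Tier.PATHOGENIC_UNKNOWN):
    return AlterationRecord(sid, gene, label, alt_class, component, tier)


@pytest.fixture(scope="session")
def study_cohort():
    """The default synthetic study cohort, n=2000, seed 1."""
    cfg = default_study_config(n_samples=2000, seed=1)
    samples, alterations, truth = generate_cohort(cfg)
    return samples, alterations, truth


@pytest.fixture(scope="session")
def study_matrix(study_cohort):
    samples, alterations, _ = study_cohort
    return build_gene_matrix(samples, alterations)


@pytest.fixture
def tiny_cohort():
    """Hand-built 8-sample cohort with one RNA-detected fusion."""
    samples = [
        make_sample("T1", tmb=5.0, pdl1_tps=0.0),
        make_sample("T2", tmb=12.0, pdl1_tps=60.0),
        make_sample("T3", "squamous", tmb=15.0, pdl1_tps=30.0),
        make_sample("T4", "squamous", tmb=None, pdl1_tps=None),
        make_sample("T5", tmb=25.0, pdl1_tps=1.0),
        make_sample("T6", tmb=3.0, pdl1_tps=49.9, rna_pass=False),
        make_sample("T7", "squamous", tmb=9.0, pdl1_tps=50.0),
        make_sample("T8", tmb=7.0, pdl1_tps=0.5, dna_pass=False),
    ]
    alterations = [
        make_alt("T1", "TP53", "R273H"),
        make_alt("T1", "KRAS", "G12C", tier=Tier.GUIDELINE_INDICATED),
        make_alt("T2", "TP53", "R175H"),
        make_alt("T3", "TP53", "R273H"),
        make_alt("T3", "PIK3CA", "E545K"),
        make_alt("T5", "ALK", "EML4-ALK", alt_class=AltClass.FUSION,
                 component=Component.RNA, tier=Tier.GUIDELINE_INDICATED),
        make_alt("T7", "KRAS", "G12V"),
    ]
    return samples, alterations
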