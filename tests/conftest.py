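"""Shared fixtures: tiny hand-written input tables and synthetic cohorts."""

from __future__ import annotations

import textwrap

import pytest

from vpbench.ingest import assemble_cohort, read_clinical_table, read_population_table, read_predictor_table
from vpbench.reference import ABCA4_HYPOMORPHS
from vpbench.synthetic_data import SyntheticConfig, generate_cohort, panel_genes


def write(path, text: str) -> str:
    path.write_text(textwrap.dedent(text).lstrip())
    return str(path)


@pytest.fixture
def predictor_file(tmp_path):
    return write(tmp_path / "predictor.tsv", """
        gene\tprotein_variant\tam_pathogenicity
        ABCA4\tp.Gly1961Glu\t0.853
        ABCA4\tp.Asn1868Ile\t0.223
        USH2A\tp.Cys3307Trp\t0.924
        RHO\tp.Pro23His\t0.981
        BRCA1\tp.Cys61Gly\t0.99
    """)


@pytest.fixture
def clinical_file(tmp_path):
    return write(tmp_path / "clinical.tsv", """
        gene\tprotein_change\tclinical_significance\treview_stars
        ABCA4\tp.Gly1961Glu\tPathogenic\t2
        ABCA4\tp.Asn1868Ile\tConflicting interpretations of pathogenicity\t1
        USH2A\tp.Cys3307Trp\tPathogenic\t1
    """)


@pytest.fixture
def population_file(tmp_path):
    return write(tmp_path / "population.tsv", """
        gene\tprotein_change\tallele_frequency\thomozygote_count\tcadd_phred
        ABCA4\tp.Gly1961Glu\t3.41e-3\t44\t26.2
        ABCA4\tp.Asn1868Ile\t5.58e-2\t2989\t23.3
        USH2A\tp.Cys3307Trp\t1.2e-5\t0\t25.0
    """)


@pytest.fixture
def hypomorph_population_file(tmp_path):
    """The nine ABCA4 hypomorph rows re-typed as a population TSV."""
    header = "gene\tprotein_change\tallele_frequency\thomozygote_count\tcadd_phred\n"
    rows = "".join(
        f"ABCA4\t{change}\t{af}\t{hom}\t{cadd}\n"
        for change, _score, af, hom, cadd in ABCA4_HYPOMORPHS
    )
    path = tmp_path / "hypomorphs.tsv"
    path.write_text(header + rows)
    return str(path)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 2-gene, 400-variant synthetic cohort assembled through ingest."""
    import tempfile

    cfg = SyntheticConfig(seed=11, n_genes=2, variants_per_gene=200)
    with tempfile.TemporaryDirectory() as d:
        files = generate_cohort(cfg, d)
        predictor = read_predictor_table(files.predictor_path, panel_genes(cfg))
        clinical = read_clinical_table(files.clinical_path)
        population = read_population_table(files.population_path)
        cohort, report = assemble_cohort(predictor, clinical, population)
    return cfg, cohort, report
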