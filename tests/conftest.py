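import numpy as np
import pandas as pd
import pytest

from azflux import DesignSpec, EffectSpec, ExpressionMatrix, SampleDesign, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-gene soybean-style RNA-seq experiment with planted effects."""
    design = DesignSpec(n_genes=300, seed=11)
    effects = EffectSpec(fold_range_log2=(4.0, 6.0))
    return generate_experiment(design, effects)


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-gene, 4-sample count matrix with a 2x2 design."""
    values = pd.DataFrame(
        {
            "AZ_t0_r1": [10, 0, 5],
            "AZ_t0_r2": [12, 0, 7],
            "AZ_t24_r1": [100, 3, 5],
            "AZ_t24_r2": [120, 1, 7],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": values.columns,
                "tissue": ["AZ"] * 4,
                "time_h": [0.0, 0.0, 24.0, 24.0],
                "replicate": [1, 2, 1, 2],
                "genotype": ["WT"] * 4,
            }
        )
    )
    return ExpressionMatrix(values, "counts"), design


def hand_labeled_annotation():
    """50 genes with hand-assigned expected categories for the keyword engine.

    Covers the GH9A1/KORRIGAN reassignment, an exclude-keyword hit,
    multi-category genes and uncategorized genes.
    """
    rows = []  # (description, expected categories)
    cases = [
        ("endo-1,4-beta-glucanase (cellulase) precursor", {"cellulases"}),
        ("cellulase family protein", {"cellulases"}),
        ("glycoside hydrolase family 9 B2", {"cellulases"}),
        ("glycoside hydrolase family 9 C3", {"cellulases"}),
        ("glycoside hydrolase 9A1 (KORRIGAN)", {"cellulose_biosynthesis"}),
        ("KORRIGAN-like endoglucanase", {"cellulose_biosynthesis"}),
        ("cellulose synthase A4", {"cellulose_biosynthesis"}),
        ("cellulose synthase-like protein", {"cellulose_biosynthesis"}),
        ("polygalacturonase precursor", {"polygalacturonases"}),
        ("probable polygalacturonase At3g15720", {"polygalacturonases"}),
        ("pectin lyase-like superfamily protein", {"polygalacturonases"}),
        ("pectate lyase 5", {"polygalacturonases"}),
        ("alpha-expansin 1", {"expansins", "expansins_alpha"}),
        ("alpha-expansin 4 precursor", {"expansins", "expansins_alpha"}),
        ("beta-expansin 3", {"expansins", "expansins_beta"}),
        ("expansin A8", {"expansins", "expansins_alpha"}),
        ("expansin B2", {"expansins", "expansins_beta"}),
        ("xyloglucan endotransglucosylase/hydrolase XTH9", {"xths"}),
        ("xyloglucan endotransglycosylase 6", {"xths"}),
        ("XTH22 (TCH4)", {"xths"}),
        ("pathogenesis-related protein PR-1", {"pr_genes"}),
        ("thaumatin-like protein", {"pr_genes"}),
        ("basic chitinase class I", {"pr_genes"}),
        ("beta-1,3-glucanase 2", {"pr_genes"}),
        ("kunitz trypsin inhibitor 1", {"pr_genes"}),
        ("photoassimilate-responsive protein PAR1 precursor", {"par1"}),
        ("PAR1 protein", {"par1"}),
        ("GDSL esterase/lipase", {"wax_suberin"}),
        ("wax synthase-like protein", {"wax_suberin"}),
        ("suberin biosynthesis protein", {"wax_suberin"}),
        ("nonspecific lipid-transfer protein LTP1", {"wax_suberin"}),
        ("fatty acyl-CoA reductase CER4", {"wax_suberin"}),
        ("class III peroxidase 42", {"peroxidase_laccase"}),
        ("laccase 4", {"peroxidase_laccase"}),
        # exclude-keyword hit: ascorbate peroxidase is excluded from the
        # peroxidase/laccase wall category
        ("L-ascorbate peroxidase, cytosolic", set()),
        ("callose synthase 5", {"callose_synthase"}),
        ("extensin-like cell wall protein", {"wall_proteins"}),
        ("arabinogalactan protein AGP9", {"wall_proteins"}),
        ("hydroxyproline-rich glycoprotein family", {"wall_proteins"}),
        ("proline-rich cell wall protein", {"wall_proteins"}),
        ("1-aminocyclopropane-1-carboxylate synthase ACS2", {"ethylene"}),
        ("1-aminocyclopropane-1-carboxylate oxidase ACO1", {"ethylene"}),
        ("auxin efflux carrier PIN3", {"auxin"}),
        ("indole-3-acetic acid-amido synthetase GH3.6", {"auxin"}),
        ("SAUR-like auxin-responsive protein", {"auxin"}),
        ("AUX/IAA transcriptional regulator", {"auxin"}),
        ("hypothetical protein", set()),
        ("unknown function DUF642 family", set()),
        ("40S ribosomal protein S3", set()),
        ("", set()),
    ]
    assert len(cases) == 50
    gene_ids = [f"g{i:02d}" for i in range(50)]
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": np.full(50, 1000),
            "description": [d for d, _ in cases],
        }
    )
    expected = {g: cats for g, (_, cats) in zip(gene_ids, cases)}
    return annotation, expected


@pytest.fixture(scope="session")
def category_fixture():
    return hand_labeled_annotation()
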