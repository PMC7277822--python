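import numpy as np
import pandas as pd
import pytest

from lumexome import SyntheticConfig, generate_expression_matrix, generate_variant_cohort


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort exercising every stage of the variant cascade."""
    return SyntheticConfig(
        seed=7,
        n_sites=500,
        n_planted_drivers=5,
        n_tumor_samples=20,
        n_control_exomes=4,
        n_genes=300,
        group_sizes={"Luminal": 40, "Others": 15, "Control": 30},
        n_group_restricted_genes={"Luminal": 20},
        n_de_genes=10,
        library_size_range=(2000, 3000),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_variant_cohort(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config):
    return generate_expression_matrix(small_config)


def make_variant_row(
    pos=100,
    ref="A",
    alt="G",
    sample_id="TUM001",
    chrom="1",
    build="hg19",
    gene="GENE00001",
    callers="FreeBayes|GATK|SAMtools",
    sift=0.01,
    polyphen2=0.99,
    mutationtaster="D",
    fathmm="D",
    cadd=25.0,
    gerp=4.1,
    **extra,
):
    row = {
        "sample_id": sample_id,
        "build": build,
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "aa_change": "p.R788Q",
        "rsid": "",
        "callers": callers,
        "quality": np.nan,
        "sift": sift,
        "polyphen2": polyphen2,
        "mutationtaster": mutationtaster,
        "fathmm": fathmm,
        "cadd": cadd,
        "gerp": gerp,
    }
    row.update(extra)
    return row


def make_variant_table(rows):
    from lumexome.io import VARIANT_COLUMNS

    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    return df
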