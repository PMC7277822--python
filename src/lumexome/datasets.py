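"""Packaged fixtures.

``driver_mutations.tsv`` transcribes a published table of 19 exonic
variants classified as breast-cancer driver mutations in a 33-patient
ductal luminal cohort (gene, nucleotide and protein change, dbSNP id,
carrier frequency, driver prediction and catalog evidence).  The table
carries no genomic coordinates, so it loads as a gene/protein-change
table rather than a full variant table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import validate_catalog


def _fixture_path(name: str):
    return resources.files("lumexome.data") / name


def load_driver_mutations() -> pd.DataFrame:
    """The 19-variant driver-mutation fixture, one row per mutation."""
    with resources.as_file(_fixture_path("driver_mutations.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    df = df.fillna("")
    df["n_carriers"] = df["n_carriers"].astype(int)
    df["n_cohort"] = df["n_cohort"].astype(int)
    return df


def load_driver_catalog() -> pd.DataFrame:
    """Driver catalog derived from the fixture: its known/reported entries.

    The two variants the original analysis flagged as new are absent, so
    classification against this catalog must rediscover them.
    """
    df = load_driver_mutations()
    known = df[df["evidence"].isin(["known", "reported"])]
    catalog = pd.DataFrame(
        {
            "gene": known["gene"],
            "aa_change": known["aa_change"],
            "status": known["evidence"],
            "evidence_note": known["population_note"],
        }
    ).reset_index(drop=True)
    return validate_catalog(catalog)
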