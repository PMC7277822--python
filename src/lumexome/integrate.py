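"""Integration of prioritized variants with expression and catalogs.

Four joins over the upstream outputs:

* :func:`join_variants_expression` — which variant-bearing genes are also
  differentially expressed, with the up/down partition of genes and SNPs.
* :func:`classify_drivers` — bookkeeping of driver predictions against a
  local driver catalog: catalogued drivers are "known" or "reported",
  driver-predicted variants absent from the catalog are "new".
  (Driver *prediction* itself is an input flag — this pipeline does not
  re-implement an external predictor.)
* :func:`intersect_cohorts` — exact mutation-site intersection between two
  cohorts, by site key within one genome build or by rsID across builds;
  silent cross-build coordinate mixing is refused.
* :func:`eqtl_test` / :func:`eqtl_scan` — mutated-vs-wildtype expression
  shift at a mutation site: two-sided Wilcoxon rank-sum on log2(CPM+0.5),
  exact null for small mutated groups, BH-adjusted across the sites of
  one scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BuildMismatchError, ValidationError
from .expression import bh_adjust
from .io import SITE_KEY, validate_catalog

PREDICTIONS = ("polymorphism", "passenger", "driver")
EVIDENCE = ("known", "reported", "new", "not_applicable")

#: Mutated-group size at or below which the exact rank-sum null is used.
EXACT_MAX_MUTATED = 10


# -- variants x differential expression ----------------------------------

def join_variants_expression(
    variants: pd.DataFrame, up_genes: set, down_genes: set
) -> tuple[pd.DataFrame, dict]:
    """Annotate variant-bearing genes with their DE status.

    Returns (gene table, summary).  The gene table has one row per gene
    with its SNP count and DE status in {up, down, none}; the summary
    reports the DE fraction as a percentage rounded to 2 decimals and the
    up/down partition of both genes and SNPs.
    """
    overlap = set(up_genes) & set(down_genes)
    if overlap:
        raise ValidationError(f"genes both up and down: {sorted(overlap)[:5]}")
    if len(variants):
        sites = variants.drop_duplicates(subset=SITE_KEY) if set(SITE_KEY) <= set(
            variants.columns
        ) else variants
        per_gene = sites.groupby("gene").size()
    else:
        per_gene = pd.Series(dtype=int)
    table = pd.DataFrame(
        {
            "gene": per_gene.index,
            "n_snps": per_gene.to_numpy(),
            "de_status": [
                "up" if g in up_genes else "down" if g in down_genes else "none"
                for g in per_gene.index
            ],
        }
    ).reset_index(drop=True)
    n_genes = len(table)
    de_table = table[table["de_status"] != "none"]
    n_de = len(de_table)
    pct = round(100.0 * n_de / n_genes, 2) if n_genes else 0.0
    summary = {
        "n_variant_genes": n_genes,
        "n_de_genes": n_de,
        "de_fraction_pct": pct,
        "n_genes_up": int((table["de_status"] == "up").sum()),
        "n_genes_down": int((table["de_status"] == "down").sum()),
        "n_snps_in_up": int(table.loc[table["de_status"] == "up", "n_snps"].sum()),
        "n_snps_in_down": int(table.loc[table["de_status"] == "down", "n_snps"].sum()),
    }
    return table, summary


# -- driver classification ------------------------------------------------

def classify_drivers(variants: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Attach catalog evidence to driver-predicted variants.

    ``variants`` must carry a ``prediction`` column in
    {polymorphism, passenger, driver}.  Driver variants found in the
    catalog on (gene, aa_change) inherit its status (known/reported);
    driver variants absent from the catalog are labeled "new"; non-driver
    variants get evidence "not_applicable".  Pure function of
    (variants, catalog): deterministic and permutation-invariant.
    """
    if "prediction" not in variants.columns:
        raise ValidationError("variants need a 'prediction' column for driver classification")
    bad = sorted(set(variants["prediction"]) - set(PREDICTIONS))
    if bad:
        raise ValidationError(f"unknown prediction values {bad}; expected {PREDICTIONS}")
    catalog = validate_catalog(catalog) if len(catalog) else catalog
    lookup = (
        dict(zip(zip(catalog["gene"], catalog["aa_change"]), catalog["status"]))
        if len(catalog)
        else {}
    )
    out = variants.copy()
    evidence = []
    for _, row in out.iterrows():
        if row["prediction"] != "driver":
            evidence.append("not_applicable")
        else:
            evidence.append(lookup.get((row["gene"], row["aa_change"]), "new"))
    out["evidence"] = evidence
    return out


def driver_summary(calls: pd.DataFrame) -> dict:
    """Headline counts over driver calls: mutations, genes, evidence split."""
    drivers = calls[calls["prediction"] == "driver"]
    return {
        "n_driver_mutations": int(len(drivers)),
        "n_driver_genes": int(drivers["gene"].nunique()),
        "n_known": int((drivers["evidence"] == "known").sum()),
        "n_reported": int((drivers["evidence"] == "reported").sum()),
        "n_new": int((drivers["evidence"] == "new").sum()),
    }


# -- cross-cohort intersection --------------------------------------------

@dataclass
class IntersectionResult:
    """Mutation sites common to two cohorts and their gene-level rollup."""

    common_sites: pd.DataFrame
    common_genes: list = field(default_factory=list)
    per_gene_counts: dict = field(default_factory=dict)

    @property
    def n_common_sites(self) -> int:
        return len(self.common_sites)


def intersect_cohorts(
    sites_a: pd.DataFrame, sites_b: pd.DataFrame, mode: str = "site"
) -> IntersectionResult:
    """Exact intersection of two cohorts' mutation sites.

    ``mode="site"`` matches on the full site key and demands a single
    genome build across both cohorts (there is no silent liftover);
    ``mode="rsid"`` matches on dbSNP identifiers and is the sanctioned
    path across builds.  Symmetric in its two arguments.
    """
    if mode not in {"site", "rsid"}:
        raise ValidationError(f"unknown intersection mode {mode!r}")
    if len(sites_a) == 0 or len(sites_b) == 0:
        empty = sites_a.head(0)
        return IntersectionResult(common_sites=empty)
    if mode == "site":
        builds = set(sites_a["build"]) | set(sites_b["build"])
        if len(builds) > 1:
            raise BuildMismatchError(
                f"site-key intersection across builds {sorted(builds)}; use rsid mode"
            )
        on = SITE_KEY
        a = sites_a.drop_duplicates(subset=on)
        b = sites_b.drop_duplicates(subset=on)
    else:
        a = sites_a[sites_a["rsid"] != ""].drop_duplicates(subset=["rsid"])
        b = sites_b[sites_b["rsid"] != ""].drop_duplicates(subset=["rsid"])
        on = ["rsid"]
    common = a.merge(b[on], on=on, how="inner")
    genes = sorted(common["gene"].unique()) if "gene" in common.columns else []
    per_gene = (
        {g: int(n) for g, n in common.groupby("gene").size().items()}
        if "gene" in common.columns
        else {}
    )
    return IntersectionResult(
        common_sites=common.reset_index(drop=True),
        common_genes=genes,
        per_gene_counts=per_gene,
    )


# -- eQTL-style mutated vs wildtype test ----------------------------------

@dataclass
class EQTLResult:
    """Expression shift between the two alleles of one mutation site."""

    site: tuple
    gene: str
    n_mutated: int
    n_wildtype: int
    effect: float        # difference of mean log2(CPM+0.5), mutated - wildtype
    pvalue: float
    padj: float = float("nan")


def eqtl_test(
    site: tuple,
    cpm: pd.DataFrame,
    mutated_samples: list,
    gene: str,
) -> EQTLResult:
    """Wilcoxon rank-sum of a gene's log2(CPM+0.5) between samples carrying
    the mutation at ``site`` and wildtype samples.

    Uses the exact rank-sum null when the mutated group has at most
    :data:`EXACT_MAX_MUTATED` samples, else the normal approximation.
    """
    if gene not in cpm.index:
        raise ValidationError(f"gene {gene!r} absent from expression matrix")
    mutated = [s for s in mutated_samples]
    if len(mutated) < 1:
        raise ValidationError("eqtl_test needs >= 1 mutated sample")
    missing = sorted(set(mutated) - set(cpm.columns))
    if missing:
        raise ValidationError(f"mutated samples without expression data: {missing}")
    expr = np.log2(cpm.loc[gene].to_numpy(dtype=float) + 0.5)
    is_mut = cpm.columns.isin(mutated)
    x, y = expr[is_mut], expr[~is_mut]
    if y.size == 0:
        raise ValidationError("eqtl_test needs >= 1 wildtype sample")
    effect = float(x.mean() - y.mean())
    if np.ptp(np.concatenate([x, y])) == 0:
        p = 1.0  # identical expression everywhere: no allelic shift
    else:
        method = "exact" if x.size <= EXACT_MAX_MUTATED else "asymptotic"
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return EQTLResult(
        site=tuple(site),
        gene=gene,
        n_mutated=int(x.size),
        n_wildtype=int(y.size),
        effect=effect,
        pvalue=p,
    )


def eqtl_scan(
    assignments: list[tuple],
    cpm: pd.DataFrame,
) -> pd.DataFrame:
    """Run :func:`eqtl_test` for each (site, gene, mutated_samples) triple
    and BH-adjust across all sites of the scan."""
    results = [eqtl_test(site, cpm, mutated, gene) for site, gene, mutated in assignments]
    if not results:
        return pd.DataFrame(
            columns=["site", "gene", "n_mutated", "n_wildtype", "effect", "pvalue", "padj"]
        )
    padj = bh_adjust([r.pvalue for r in results])
    rows = []
    for r, q in zip(results, padj):
        r.padj = float(q)
        rows.append(
            {
                "site": "_".join(map(str, r.site)),
                "gene": r.gene,
                "n_mutated": r.n_mutated,
                "n_wildtype": r.n_wildtype,
                "effect": r.effect,
                "pvalue": r.pvalue,
                "padj": r.padj,
            }
        )
    return pd.DataFrame(rows)


# -- full integration bundle ----------------------------------------------

def run_integration(
    variants: pd.DataFrame,
    catalog: pd.DataFrame,
    up_genes: set | None = None,
    down_genes: set | None = None,
    de_padj: pd.Series | None = None,
    cohort_b: pd.DataFrame | None = None,
    cpm: pd.DataFrame | None = None,
    eqtl_assignments: list | None = None,
    intersect_mode: str = "site",
    out_dir: str | Path | None = None,
) -> dict:
    """Run every integration step available for the supplied inputs.

    Returns a bundle dict with the joined gene table, driver calls,
    intersection result, eQTL table, the chromosome-location table for a
    genome-wide significance plot (gene, chromosome, -log10 padj,
    direction), and a JSON-ready summary of every headline count.  When
    ``out_dir`` is given, each table is written as TSV plus
    ``summary.json``.
    """
    up_genes = up_genes or set()
    down_genes = down_genes or set()
    bundle: dict = {"summary": {"schema_version": 1}}

    gene_table, join_summary = join_variants_expression(variants, up_genes, down_genes)
    bundle["gene_table"] = gene_table
    bundle["summary"]["expression_overlap"] = join_summary

    if "prediction" in variants.columns:
        calls = classify_drivers(variants, catalog)
    else:
        calls = variants.copy()
        calls["prediction"] = "passenger"
        calls["evidence"] = "not_applicable"
    bundle["driver_calls"] = calls
    bundle["summary"]["drivers"] = driver_summary(calls)

    if cohort_b is not None:
        inter = intersect_cohorts(variants, cohort_b, mode=intersect_mode)
        bundle["intersection"] = inter
        bundle["summary"]["intersection"] = {
            "n_common_sites": inter.n_common_sites,
            "n_common_genes": len(inter.common_genes),
            "multi_mutation_genes": {
                g: n for g, n in inter.per_gene_counts.items() if n > 1
            },
        }

    if cpm is not None and eqtl_assignments:
        eqtl = eqtl_scan(eqtl_assignments, cpm)
        bundle["eqtl"] = eqtl
        bundle["summary"]["eqtl"] = {
            "n_sites_tested": int(len(eqtl)),
            "n_significant_padj_05": int((eqtl["padj"] < 0.05).sum()),
        }

    # chromosome-location table for the genome-wide significance view
    if de_padj is not None and len(gene_table) and "chrom" in variants.columns:
        chrom_of = (
            variants.drop_duplicates(subset=["gene"]).set_index("gene")["chrom"]
        )
        rows = []
        for _, r in gene_table.iterrows():
            if r["de_status"] == "none" or r["gene"] not in de_padj.index:
                continue
            padj = float(de_padj.loc[r["gene"]])
            rows.append(
                {
                    "gene": r["gene"],
                    "chromosome": chrom_of.get(r["gene"], ""),
                    "neg_log10_padj": -np.log10(max(padj, 1e-300)),
                    "direction": r["de_status"],
                }
            )
        bundle["chromosome_table"] = pd.DataFrame(
            rows, columns=["gene", "chromosome", "neg_log10_padj", "direction"]
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["gene_table"].to_csv(out / "gene_table.tsv", sep="\t", index=False)
        bundle["driver_calls"].to_csv(out / "driver_calls.tsv", sep="\t", index=False)
        if "intersection" in bundle:
            bundle["intersection"].common_sites.to_csv(
                out / "intersection.tsv", sep="\t", index=False
            )
        if "eqtl" in bundle:
            bundle["eqtl"].to_csv(out / "eqtl.tsv", sep="\t", index=False)
        if "chromosome_table" in bundle:
            bundle["chromosome_table"].to_csv(
                out / "chromosome_locations.tsv", sep="\t", index=False
            )
        (out / "summary.json").write_text(json.dumps(bundle["summary"], indent=2, sort_keys=True))
    return bundle
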