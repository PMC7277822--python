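"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators cover the two arms of the pipeline:

* :func:`generate_variant_cohort` emulates multi-sample tumor variant tables
  plus control-tissue exomes: every site carries per-caller support, a
  configurable fraction of sites is germline-contaminated (present in at
  least one control exome), a small number of *planted drivers* receives
  pathogenicity profiles beyond all six filter thresholds with extreme
  quantitative scores, and a truth table labels every site.

* :func:`generate_expression_matrix` emulates a bulk RNA-seq raw-count
  matrix over the three sample groups {Luminal, Others, Control}: counts
  are negative-binomial with per-sample library sizes, *group-restricted*
  genes are expressed in a bursty minority of samples of their group
  pattern only (so the low-expression filter removes them while their group
  mean stays high), and planted differentially expressed genes carry a
  log2 mean shift between Luminal and Control.

All randomness flows from a single seed; each output table draws from its
own deterministically derived sub-stream, so adding one output never
perturbs the others.  Identical config implies byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError
from .io import (
    SITE_KEY,
    VARIANT_COLUMNS,
    empty_variant_table,
    write_driver_catalog,
    write_variants,
)

_CHROMS = [str(c) for c in range(1, 23)] + ["X"]
_AA = list("ARNDCQEGHILKMFPSTWYV")
_CALLER_FULL = "FreeBayes|GATK|SAMtools"

#: Truth labels for variant sites, by removal stage / pathogenicity class.
SITE_LABELS = ("consensus-fail", "germline", "benign", "pathogenic-low", "pathogenic-driver")

#: The six group-restriction patterns (groups whose mean is above threshold).
RESTRICTED_PATTERNS = (
    "Luminal", "Others", "Control",
    "Luminal+Others", "Luminal+Control", "Others+Control",
)

_DEFAULT_RESTRICTED = {
    "Luminal": 159,
    "Control": 224,
    "Others": 285,
    "Others+Control": 22,
    "Luminal+Others": 79,
    "Luminal+Control": 11,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohorts.

    Defaults mirror the study conditions this pipeline targets: 33 tumor
    exomes with 7 control-tissue exomes, roughly a third of tumor variants
    germline-contaminated, and an expression cohort of 510 Luminal, 260
    other-subtype and 89 control samples with the six recovered-gene
    patterns populated at 159/224/285/22/79/11 genes.
    """

    seed: int = 0

    # variant cohort
    n_tumor_samples: int = 33
    n_control_exomes: int = 7
    n_sites: int = 1000
    germline_fraction: float = 0.31
    consensus_fail_fraction: float = 0.10
    pathogenic_low_fraction: float = 0.05
    n_planted_drivers: int = 5
    missing_score_fraction: float = 0.05
    build: str = "hg19"
    #: Optional subtype composition, e.g. {"ductal_luminal": 33, "other": 19};
    #: None tags every tumor sample "ductal_luminal".
    subtype_counts: dict | None = None

    # driver catalog
    catalog_known_fraction: float = 0.2
    catalog_reported_fraction: float = 0.6

    # expression matrix
    n_genes: int = 5000
    group_sizes: dict = field(
        default_factory=lambda: {"Luminal": 510, "Others": 260, "Control": 89}
    )
    n_group_restricted_genes: dict = field(default_factory=lambda: dict(_DEFAULT_RESTRICTED))
    n_de_genes: int = 50
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    #: Min/max expected total counts per sample.
    library_size_range: tuple = (35_000, 45_000)
    #: Target per-group mean (counts) of a restricted gene within its pattern.
    restricted_group_mean: float = 15.0
    #: Mean count of a restricted gene in the few samples that express it.
    restricted_burst_mean: float = 300.0

    def validate(self) -> "SyntheticConfig":
        counts = {
            "n_tumor_samples": self.n_tumor_samples,
            "n_control_exomes": self.n_control_exomes,
            "n_sites": self.n_sites,
            "n_planted_drivers": self.n_planted_drivers,
            "n_genes": self.n_genes,
            "n_de_genes": self.n_de_genes,
        }
        for name, v in counts.items():
            if v < 0:
                raise InvalidConfigError(f"{name} must be >= 0, got {v}")
        for name in ("germline_fraction", "consensus_fail_fraction",
                     "pathogenic_low_fraction", "missing_score_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0,1], got {v}")
        if self.dispersion <= 0:
            raise InvalidConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if self.n_planted_drivers > self.n_sites:
            raise InvalidConfigError(
                f"n_planted_drivers={self.n_planted_drivers} exceeds n_sites={self.n_sites}"
            )
        if any(v < 0 for v in self.group_sizes.values()):
            raise InvalidConfigError("group sizes must be >= 0")
        unknown = set(self.n_group_restricted_genes) - set(RESTRICTED_PATTERNS)
        if unknown:
            raise InvalidConfigError(f"unknown restriction patterns {sorted(unknown)}")
        n_special = sum(self.n_group_restricted_genes.values()) + self.n_de_genes
        if n_special > self.n_genes:
            raise InvalidConfigError(
                f"restricted + DE genes ({n_special}) exceed n_genes ({self.n_genes})"
            )
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise InvalidConfigError(f"bad library_size_range {self.library_size_range}")
        if self.subtype_counts is not None:
            if sum(self.subtype_counts.values()) != self.n_tumor_samples:
                raise InvalidConfigError("subtype_counts must sum to n_tumor_samples")
        return self


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # per-table sub-stream: seeding on (seed, stream) keeps tables independent
    return np.random.default_rng([config.seed, stream])


def tumor_sample_ids(config: SyntheticConfig) -> list[str]:
    return [f"TUM{i:03d}" for i in range(1, config.n_tumor_samples + 1)]


def control_sample_ids(config: SyntheticConfig) -> list[str]:
    return [f"CTL{i:02d}" for i in range(1, config.n_control_exomes + 1)]


def sample_metadata(config: SyntheticConfig) -> pd.DataFrame:
    """Tumor sample metadata (sample_id, subtype) per the configured composition."""
    config.validate()
    ids = tumor_sample_ids(config)
    if config.subtype_counts is None:
        subtypes = ["ductal_luminal"] * len(ids)
    else:
        subtypes = [s for s, n in config.subtype_counts.items() for _ in range(n)]
    return pd.DataFrame({"sample_id": ids, "subtype": subtypes})


# -- pathogenicity score sampling ---------------------------------------

def _passing_scores(rng, extreme: bool) -> dict:
    """Scores beyond all six thresholds; extreme values for planted drivers.

    Driver and non-driver ranges are disjoint so drivers sit strictly in the
    most-pathogenic tail of every quantitative tool.
    """
    if extreme:
        return {
            "sift": rng.uniform(0.0, 0.004),
            "polyphen2": rng.uniform(0.996, 1.0),
            "mutationtaster": rng.choice(["A", "D"]),
            "fathmm": "D",
            "cadd": rng.uniform(36.0, 50.0),
            "gerp": rng.uniform(5.6, 6.5),
        }
    return {
        "sift": rng.uniform(0.005, 0.0499),
        "polyphen2": rng.uniform(0.98, 0.995),
        "mutationtaster": rng.choice(["A", "D"]),
        "fathmm": "D",
        "cadd": rng.uniform(20.0, 35.0),
        "gerp": rng.uniform(2.0, 5.5),
    }


def _failing_value(rng, tool: str):
    return {
        "sift": lambda: rng.uniform(0.05, 1.0),
        "polyphen2": lambda: rng.uniform(0.0, 0.9799),
        "mutationtaster": lambda: rng.choice(["N", "P"]),
        "fathmm": lambda: "T",
        "cadd": lambda: rng.uniform(0.0, 19.99),
        "gerp": lambda: rng.uniform(-3.0, 1.99),
    }[tool]()


def _benign_scores(rng, missing_fraction: float) -> dict:
    scores = _passing_scores(rng, extreme=False)
    tools = list(scores)
    n_fail = int(rng.integers(1, 7))
    for tool in rng.choice(tools, size=n_fail, replace=False):
        scores[tool] = _failing_value(rng, tool)
    for tool in tools:
        if rng.uniform() < missing_fraction:
            scores[tool] = "" if tool in ("mutationtaster", "fathmm") else math.nan
    return scores


def _passes_all_six(scores: dict) -> bool:
    try:
        return (
            not pd.isna(scores["sift"]) and scores["sift"] < 0.05
            and not pd.isna(scores["polyphen2"]) and scores["polyphen2"] >= 0.98
            and scores["mutationtaster"] in ("A", "D")
            and scores["fathmm"] == "D"
            and not pd.isna(scores["cadd"]) and scores["cadd"] >= 20
            and not pd.isna(scores["gerp"]) and scores["gerp"] >= 2
        )
    except TypeError:
        return False


# -- variant cohort ------------------------------------------------------

def generate_variant_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (tumor variant table, control variant sets, truth table).

    The truth table labels every site with one of :data:`SITE_LABELS`:
    sites removed by caller consensus, sites shared with a control exome
    (germline contamination), sites failing the six-tool pathogenicity
    filter (benign), and pathogenic sites split into moderate
    (pathogenic-low) and planted extreme (pathogenic-driver) profiles.
    The labels are disjoint and score-consistent by construction; germline
    assignment prefers non-driver sites, spilling into drivers only when
    ``germline_fraction`` forces it.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_sites
    truth_cols = SITE_KEY + [
        "gene", "aa_change", "rsid", "label",
        "in_control", "full_consensus", "passes_all_six", "n_tumor_samples",
    ]
    if n == 0:
        controls = pd.DataFrame(columns=["sample_id", *SITE_KEY])
        return empty_variant_table(), controls, pd.DataFrame(columns=truth_cols)

    # unique site keys: globally unique positions make (chrom, pos) unique
    pos = np.sort(rng.choice(np.arange(1, 10_000_001), size=n, replace=False))
    chrom = rng.choice(_CHROMS, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    bases = np.array(list("ACGT"))
    gene = np.array([f"GENE{i + 1:05d}" for i in rng.integers(0, config.n_genes, size=n)])
    aa = [
        f"p.{rng.choice(_AA)}{int(rng.integers(1, 1200))}{rng.choice(_AA)}"
        for _ in range(n)
    ]
    rs_numbers = np.unique(rng.integers(10**6, 10**9, size=2 * n))
    rs_numbers = rng.permutation(rs_numbers)[:n]
    rsid = np.where(rng.uniform(size=n) < 0.5,
                    [f"rs{v}" for v in rs_numbers], "")

    # disjoint label allocation
    order = rng.permutation(n)
    drivers = list(order[: config.n_planted_drivers])
    rest = list(order[config.n_planted_drivers:])
    n_germ = round(config.germline_fraction * n)
    if n_germ > len(rest):  # forced: germline contamination reaches planted drivers
        extra = n_germ - len(rest)
        germ = rest + drivers[:extra]
        drivers = drivers[extra:]
        rest = []
    else:
        germ = rest[:n_germ]
        rest = rest[n_germ:]
    n_cf = round(config.consensus_fail_fraction * len(rest))
    consensus_fail = rest[:n_cf]
    rest = rest[n_cf:]
    n_low = round(config.pathogenic_low_fraction * len(rest))
    low = rest[:n_low]
    benign = rest[n_low:]

    label = np.empty(n, dtype=object)
    label[drivers] = "pathogenic-driver"
    label[germ] = "germline"
    label[consensus_fail] = "consensus-fail"
    label[low] = "pathogenic-low"
    label[benign] = "benign"

    scores = [None] * n
    for i in range(n):
        if label[i] == "pathogenic-driver":
            scores[i] = _passing_scores(rng, extreme=True)
        elif label[i] == "pathogenic-low":
            scores[i] = _passing_scores(rng, extreme=False)
        elif label[i] == "benign":
            scores[i] = _benign_scores(rng, config.missing_score_fraction)
        else:  # germline / consensus-fail: mixed profiles, removed upstream anyway
            scores[i] = (
                _passing_scores(rng, extreme=False)
                if rng.uniform() < 0.5
                else _benign_scores(rng, config.missing_score_fraction)
            )

    full_consensus = label != "consensus-fail"
    callers = np.empty(n, dtype=object)
    parts = _CALLER_FULL.split("|")
    for i in range(n):
        if full_consensus[i]:
            callers[i] = _CALLER_FULL
        else:
            k = int(rng.integers(1, 3))
            callers[i] = "|".join(sorted(rng.choice(parts, size=k, replace=False)))

    truth = pd.DataFrame(
        {
            "build": config.build,
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "gene": gene,
            "aa_change": aa,
            "rsid": rsid,
            "label": label,
            "in_control": np.isin(np.arange(n), germ),
            "full_consensus": full_consensus,
            "passes_all_six": [_passes_all_six(s) for s in scores],
            "n_tumor_samples": 0,
        }
    )

    # tumor rows: each site observed in >= 1 tumor sample
    tum_ids = tumor_sample_ids(config)
    rows = []
    n_carriers = 1 + rng.binomial(2, 0.3, size=n)
    n_carriers = np.minimum(n_carriers, max(1, len(tum_ids)))
    for i in range(n):
        carriers = rng.choice(tum_ids, size=n_carriers[i], replace=False)
        for s in sorted(carriers):
            rows.append(
                {
                    "sample_id": s,
                    "build": config.build,
                    "chrom": chrom[i],
                    "pos": int(pos[i]),
                    "ref": bases[ref_idx[i]],
                    "alt": bases[alt_idx[i]],
                    "gene": gene[i],
                    "aa_change": aa[i],
                    "rsid": rsid[i],
                    "callers": callers[i],
                    "quality": float(np.round(rng.uniform(100.0, 3000.0), 2)),
                    **scores[i],
                }
            )
    tumor = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    tumor["pos"] = tumor["pos"].astype(np.int64)
    truth["n_tumor_samples"] = n_carriers

    # control exomes: germline sites only
    ctl_ids = control_sample_ids(config)
    ctl_rows = []
    for i in germ:
        if not ctl_ids:
            break
        k = 1 + int(rng.binomial(len(ctl_ids) - 1, 0.3)) if len(ctl_ids) > 1 else 1
        for s in sorted(rng.choice(ctl_ids, size=k, replace=False)):
            ctl_rows.append(
                {
                    "sample_id": s,
                    "build": config.build,
                    "chrom": chrom[i],
                    "pos": int(pos[i]),
                    "ref": bases[ref_idx[i]],
                    "alt": bases[alt_idx[i]],
                }
            )
    controls = pd.DataFrame(ctl_rows, columns=["sample_id", *SITE_KEY])
    if len(controls):
        controls = controls.sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)
        controls["pos"] = controls["pos"].astype(np.int64)
    return tumor, controls, truth


# -- expression matrix ---------------------------------------------------

def _pattern_groups(pattern: str) -> list[str]:
    return pattern.split("+")


def generate_expression_matrix(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate (raw count matrix genes x samples, group labels, gene truth table).

    Counts are negative-binomial with gene-level base means drawn lognormal
    (median ~2.25 counts, a long upper tail) and per-sample expected library
    sizes uniform in ``library_size_range``.  Restricted genes are expressed
    only in the few samples of their pattern groups needed to push the group
    mean to ``restricted_group_mean``; planted DE genes multiply the Luminal
    mean by ``2**effect_log2fc``.
    """
    config.validate()
    if sum(config.group_sizes.values()) == 0:
        raise InvalidConfigError("group_sizes sum to 0: no samples to generate")
    rng = _rng(config, 1)

    genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    samples, groups = [], []
    prefixes = {"Luminal": "LUM", "Others": "OTH", "Control": "CTR"}
    for g, size in config.group_sizes.items():
        for i in range(size):
            samples.append(f"{prefixes.get(g, g[:3].upper())}{i + 1:04d}")
            groups.append(g)
    groups = pd.Series(groups, index=samples, name="group")
    n_g, n_s = len(genes), len(samples)

    # assign special genes
    order = rng.permutation(n_g)
    cursor = 0
    restricted: dict[int, str] = {}
    for pattern in RESTRICTED_PATTERNS:
        k = config.n_group_restricted_genes.get(pattern, 0)
        for i in order[cursor:cursor + k]:
            restricted[i] = pattern
        cursor += k
    de_genes = set(order[cursor:cursor + config.n_de_genes])

    base = rng.lognormal(mean=math.log(2.25), sigma=1.6, size=n_g)
    base[list(restricted)] = 0.03  # near-zero off-pattern baseline
    if de_genes:
        # planted effects sit on well-expressed genes
        base[list(de_genes)] = rng.lognormal(mean=math.log(40.0), sigma=0.8, size=len(de_genes))

    mu = np.tile(base[:, None], (1, n_s))
    group_arr = groups.to_numpy()
    lum_mask = group_arr == "Luminal"
    if de_genes:
        mu[np.ix_(list(de_genes), lum_mask)] *= 2.0 ** config.effect_log2fc

    n_expressing = np.zeros(n_g, dtype=int)
    for i, pattern in restricted.items():
        for g in _pattern_groups(pattern):
            members = np.flatnonzero(group_arr == g)
            if len(members) == 0:
                raise InvalidConfigError(f"restriction pattern {pattern!r} needs samples in group {g!r}")
            k = min(
                len(members),
                math.ceil(len(members) * config.restricted_group_mean / config.restricted_burst_mean),
            )
            chosen = rng.choice(members, size=k, replace=False)
            mu[i, chosen] = config.restricted_burst_mean
            n_expressing[i] += k

    # per-sample sequencing depth relative to the baseline expectation; group
    # effects and bursts then shift totals slightly, as composition does in
    # real libraries (this is what TMM corrects)
    lib = rng.uniform(*config.library_size_range, size=n_s)
    mu *= lib / base.sum()

    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)

    truth = pd.DataFrame(
        {
            "gene": genes,
            "base_mean": base,
            "pattern": [restricted.get(i, "") for i in range(n_g)],
            "is_de": [i in de_genes for i in range(n_g)],
            "effect_log2fc": [config.effect_log2fc if i in de_genes else 0.0 for i in range(n_g)],
            "n_expressing": n_expressing,
        }
    )
    return counts_df, groups, truth


# -- driver catalog ------------------------------------------------------

def generate_driver_catalog(truth: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Catalog a subset of planted drivers as known/reported; rest stay absent.

    Downstream driver classification must label the absent remainder "new".
    """
    config.validate()
    rng = _rng(config, 2)
    drivers = truth.loc[truth["label"] == "pathogenic-driver", ["gene", "aa_change"]]
    drivers = drivers.drop_duplicates().reset_index(drop=True)
    k = len(drivers)
    n_known = math.floor(k * config.catalog_known_fraction)
    n_reported = math.floor(k * config.catalog_reported_fraction)
    order = rng.permutation(k)
    entries = []
    for j, i in enumerate(order[: n_known + n_reported]):
        status = "known" if j < n_known else "reported"
        entries.append(
            {
                "gene": drivers.iloc[i]["gene"],
                "aa_change": drivers.iloc[i]["aa_change"],
                "status": status,
                "evidence_note": "synthetic catalog entry",
            }
        )
    catalog = pd.DataFrame(entries, columns=["gene", "aa_change", "status", "evidence_note"])
    return catalog.sort_values(["gene", "aa_change"]).reset_index(drop=True)


# -- on-disk cohort ------------------------------------------------------

def write_cohort(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate everything and write it under ``out_dir``.

    Layout: per-tumor-sample VCFs plus one flat tumor TSV, a control-site
    TSV, truth tables, the expression counts/groups TSVs, the driver
    catalog, sample metadata and a YAML snapshot of the config.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tumor, controls, vtruth = generate_variant_cohort(config)
    counts, groups, etruth = generate_expression_matrix(config)
    catalog = generate_driver_catalog(vtruth, config)
    meta = sample_metadata(config)

    paths: dict[str, Path] = {}
    vcf_dir = out / "tumor_vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample, part in tumor.groupby("sample_id", sort=True):
        write_variants(part.reset_index(drop=True), vcf_dir / f"{sample}.vcf", "vcf")
    paths["tumor_vcf_dir"] = vcf_dir
    paths["tumor_tsv"] = write_variants(tumor, out / "tumor_variants.tsv", "tsv")
    controls.to_csv(out / "control_sites.tsv", sep="\t", index=False)
    paths["control_tsv"] = out / "control_sites.tsv"
    vtruth.to_csv(out / "variant_truth.tsv", sep="\t", index=False)
    paths["variant_truth"] = out / "variant_truth.tsv"
    counts.to_csv(out / "counts.tsv", sep="\t")
    paths["counts"] = out / "counts.tsv"
    groups.rename("group").to_frame().rename_axis("sample_id").to_csv(
        out / "groups.tsv", sep="\t"
    )
    paths["groups"] = out / "groups.tsv"
    etruth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)
    paths["expression_truth"] = out / "expression_truth.tsv"
    paths["catalog"] = write_driver_catalog(catalog, out / "driver_catalog.tsv")
    meta.to_csv(out / "sample_metadata.tsv", sep="\t", index=False)
    paths["metadata"] = out / "sample_metadata.tsv"
    cfg = asdict(config)
    cfg["library_size_range"] = list(config.library_size_range)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths["config"] = out / "config.yaml"
    return paths
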