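"""The somatic-variant prioritization cascade.

Five stages, applied in order, each a pure set-shrinking function on a
variant table (rows = (sample, site) observations, identity = the site key
``(build, chrom, pos, ref, alt)``):

1. **Caller consensus** — keep only calls supported by all three callers
   (GATK, SAMtools, FreeBayes).  Discordant sites are logged for audit
   rather than manually curated: strictness buys reproducibility.
2. **Germline subtraction** — discard every tumor site observed in at
   least one control-tissue exome.  Removal is by site, not by sample, and
   ignores zygosity.
3. **Six-tool pathogenicity filter** — retain a variant only if it passes
   all of SIFT < 0.05, PolyPhen-2 >= 0.98, MutationTaster in {A, D},
   FATHMM = D, CADD >= 20 and GERP++ >= 2.  A missing score fails its
   tool (conservative).
4. **Percentile pruning** — per quantitative tool (SIFT, PolyPhen-2,
   CADD, GERP++), drop the least-pathogenic fraction ``q`` of distinct
   sites; a site survives only if it is on the pathogenic side of (or tied
   with) the empirical q-quantile boundary for *every* tool.  Presets
   q = 0.10 and q = 0.20.
5. **Subtype subsetting** — keep variants observed in samples of the
   target tumor subtype.

Quantile boundaries use the linearly interpolated empirical quantile over
distinct sites; boundary ties are retained.  Both choices make the stage
deterministic and invariant to row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BuildMismatchError, ValidationError
from .io import KNOWN_CALLERS, QUANTITATIVE_SCORES, SITE_KEY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Pathogenicity cutoffs of the six-tool filter."""

    sift_max: float = 0.05            # exclusive: pass iff sift < sift_max
    polyphen2_min: float = 0.98       # inclusive
    mutationtaster_pass: frozenset = frozenset({"A", "D"})
    fathmm_pass: frozenset = frozenset({"D"})
    cadd_min: float = 20.0            # inclusive
    gerp_min: float = 2.0             # inclusive

    def validate(self) -> "FilterThresholds":
        if not 0 < self.sift_max <= 1:
            raise ValidationError(f"sift_max must be in (0,1], got {self.sift_max}")
        if not 0 <= self.polyphen2_min <= 1:
            raise ValidationError(f"polyphen2_min must be in [0,1], got {self.polyphen2_min}")
        if self.cadd_min < 0:
            raise ValidationError(f"cadd_min must be >= 0, got {self.cadd_min}")
        if not set(self.mutationtaster_pass) <= {"A", "D", "N", "P"}:
            raise ValidationError("mutationtaster_pass outside {A,D,N,P}")
        if not set(self.fathmm_pass) <= {"D", "T"}:
            raise ValidationError("fathmm_pass outside {D,T}")
        return self


@dataclass(frozen=True)
class PruneConfig:
    """Percentile-pruning step: drop the least-pathogenic fraction ``q``.

    ``q=0.10`` and ``q=0.20`` are the two preset strengths; both apply the
    all-four-tools consensus retention rule.
    """

    q: float = 0.20
    tools: tuple = tuple(QUANTITATIVE_SCORES)

    def validate(self) -> "PruneConfig":
        if not 0 <= self.q < 1:
            raise ValidationError(f"prune fraction q must be in [0,1), got {self.q}")
        unknown = set(self.tools) - set(QUANTITATIVE_SCORES)
        if unknown:
            raise ValidationError(f"unknown prune tools {sorted(unknown)}")
        return self


@dataclass
class CascadeReport:
    """Per-stage record/site/gene counts; counts never increase downstream."""

    stages: list = field(default_factory=list)

    def log(self, name: str, df: pd.DataFrame) -> None:
        self.stages.append(
            {
                "stage": name,
                "n_records": int(len(df)),
                "n_sites": int(df[SITE_KEY].drop_duplicates().shape[0]) if len(df) else 0,
                "n_genes": int(df["gene"].nunique()) if len(df) else 0,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_records", "n_sites", "n_genes"])


def consensus_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records supported by all three callers (strict intersection)."""
    if len(records) == 0:
        return records.copy()
    if (records["callers"] == "").any():
        bad = records.index[records["callers"] == ""].tolist()
        raise ValidationError(f"records with empty caller set at rows {bad}")
    sets = records["callers"].map(lambda s: frozenset(s.split("|")))
    keep = sets == frozenset(KNOWN_CALLERS)
    discordant = records.loc[~keep, SITE_KEY].drop_duplicates()
    if len(discordant):
        logger.info("consensus_filter: %d discordant sites removed", len(discordant))
    return records.loc[keep].copy()


def germline_subtract(tumor: pd.DataFrame, controls: pd.DataFrame) -> pd.DataFrame:
    """Remove every tumor record whose site occurs in any control exome."""
    if len(tumor) == 0 or len(controls) == 0:
        return tumor.copy()
    builds = set(tumor["build"]) | set(controls["build"])
    if len(builds) > 1:
        raise BuildMismatchError(
            f"germline subtraction requires a single genome build, got {sorted(builds)}"
        )
    control_keys = set(map(tuple, controls[SITE_KEY].drop_duplicates().to_numpy()))
    keys = list(map(tuple, tumor[SITE_KEY].to_numpy()))
    keep = [k not in control_keys for k in keys]
    return tumor.loc[keep].copy()


def pathogenicity_mask(records: pd.DataFrame, thresholds: FilterThresholds) -> pd.Series:
    """Boolean pass/fail of the six-tool filter; missing scores fail their tool."""
    thresholds.validate()
    sift = records["sift"].to_numpy(dtype=float)
    pp2 = records["polyphen2"].to_numpy(dtype=float)
    cadd = records["cadd"].to_numpy(dtype=float)
    gerp = records["gerp"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok = (
            (sift < thresholds.sift_max)           # NaN compares False: missing fails
            & (pp2 >= thresholds.polyphen2_min)
            & records["mutationtaster"].isin(thresholds.mutationtaster_pass).to_numpy()
            & records["fathmm"].isin(thresholds.fathmm_pass).to_numpy()
            & (cadd >= thresholds.cadd_min)
            & (gerp >= thresholds.gerp_min)
        )
    return pd.Series(ok, index=records.index)


def pathogenicity_filter(
    records: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Retain records passing all six pathogenicity criteria."""
    thresholds = thresholds or FilterThresholds()
    if len(records) == 0:
        return records.copy()
    return records.loc[pathogenicity_mask(records, thresholds)].copy()


#: Pathogenicity orientation: -1 when low scores are pathogenic (SIFT).
_ORIENTATION = {"sift": -1, "polyphen2": 1, "cadd": 1, "gerp": 1}


def percentile_prune(records: pd.DataFrame, prune: PruneConfig | None = None) -> pd.DataFrame:
    """Drop sites in the least-pathogenic q-tail of any quantitative tool.

    Quantile boundaries are computed over *distinct sites* (sample
    multiplicity does not weight them) with linear interpolation; a site is
    retained iff for every tool its score is strictly more pathogenic than,
    or exactly tied with, the boundary.
    """
    prune = (prune or PruneConfig()).validate()
    if len(records) == 0 or prune.q == 0:
        return records.copy()
    sites = records.drop_duplicates(subset=SITE_KEY)
    for tool in prune.tools:
        if sites[tool].isna().any():
            raise ValidationError(
                f"percentile_prune requires {tool} for every site; "
                "missing scores must have been removed by the pathogenicity filter"
            )
    keep_sites = np.ones(len(sites), dtype=bool)
    for tool in prune.tools:
        values = sites[tool].to_numpy(dtype=float)
        if _ORIENTATION[tool] > 0:
            boundary = np.quantile(values, prune.q)
            keep_sites &= values >= boundary
        else:
            boundary = np.quantile(values, 1.0 - prune.q)
            keep_sites &= values <= boundary
    retained = set(map(tuple, sites.loc[keep_sites, SITE_KEY].to_numpy()))
    keys = list(map(tuple, records[SITE_KEY].to_numpy()))
    return records.loc[[k in retained for k in keys]].copy()


def subset_by_subtype(
    records: pd.DataFrame, metadata: pd.DataFrame, subtype: str
) -> pd.DataFrame:
    """Keep records from samples of the given subtype.

    ``metadata`` maps sample_id -> subtype; every sample present in the
    records must be covered.
    """
    if len(records) == 0:
        return records.copy()
    mapping = dict(zip(metadata["sample_id"], metadata["subtype"]))
    unknown = sorted(set(records["sample_id"]) - set(mapping))
    if unknown:
        raise ValidationError(f"samples missing from metadata: {unknown}")
    keep = records["sample_id"].map(mapping) == subtype
    return records.loc[keep].copy()


def run_cascade(
    tumor: pd.DataFrame,
    controls: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    prune: PruneConfig | None = None,
    metadata: pd.DataFrame | None = None,
    subtype: str | None = None,
    min_quality: float | None = None,
) -> tuple[pd.DataFrame, CascadeReport]:
    """Apply the full cascade; returns the surviving records and a stage report.

    ``min_quality`` optionally gates records on the caller quality column
    before the cascade (off by default; quality control is normally
    upstream of this pipeline).
    """
    report = CascadeReport()
    df = tumor.copy()
    report.log("input", df)
    if min_quality is not None:
        df = df.loc[df["quality"].fillna(-np.inf) >= min_quality].copy()
        report.log("quality", df)
    df = consensus_filter(df)
    report.log("consensus", df)
    df = germline_subtract(df, controls)
    report.log("germline_subtracted", df)
    df = pathogenicity_filter(df, thresholds)
    report.log("pathogenicity", df)
    df = percentile_prune(df, prune)
    report.log("percentile_pruned", df)
    if subtype is not None:
        if metadata is None:
            raise ValidationError("subtype subsetting requires sample metadata")
        df = subset_by_subtype(df, metadata, subtype)
        report.log(f"subtype[{subtype}]", df)
    return df.reset_index(drop=True), report
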