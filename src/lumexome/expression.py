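"""Expression-side pipeline: low-expression filtering, group-wise gene
recovery, TMM/CPM normalization and a two-configuration differential-
expression engine.

The flow on a raw gene x sample count matrix with group labels
{Luminal, Others, Control}:

1. :func:`base_expression_filter` — the published ``filterByExpr`` rule of
   Chen et al.: keep a gene iff its CPM exceeds a cutoff derived from
   ``min_count`` and the median library size in at least (smallest group
   size) samples, and its total count exceeds ``min_total_count``.
2. :func:`compute_recovery_threshold` / :func:`recover_genes` — the
   recovery protocol for genes expressed in only one or two groups: the
   threshold is 3x the median of per-gene mean raw counts over all genes
   and samples; a filtered-out gene whose group mean exceeds the threshold
   in exactly one or two groups is recovered, bookkept by group pattern.
3. :func:`tmm_normalize` — trimmed mean of M-values (Robinson & Oshlack)
   scale factors (30% M-trim, 5% A-trim, precision-weighted), rescaled to
   unit geometric mean, then CPM = count / (library size x factor) x 1e6.
4. :func:`differential_expression` — per-gene Luminal-vs-Control contrast
   on log2(CPM + 0.5) under two configurations (Welch t and Wilcoxon
   rank-sum), Benjamini-Hochberg adjusted; :func:`select_significant`
   keeps genes significant under BOTH configurations with concordant
   fold-change sign, mirroring a two-method consensus design.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("Luminal", "Others", "Control")


def validate_matrix(counts: pd.DataFrame, groups: pd.Series) -> None:
    """Check the count-matrix invariants: unique genes, labeled samples,
    non-negative counts."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene symbols: {dup[:5]}")
    unlabeled = [s for s in counts.columns if s not in groups.index]
    if unlabeled:
        raise ValidationError(f"samples without group label: {unlabeled[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts")


# -- base low-expression filter ------------------------------------------

def base_expression_filter(
    counts: pd.DataFrame,
    groups: pd.Series,
    min_count: float = 10.0,
    min_total_count: float = 15.0,
    large_n: int = 10,
    min_prop: float = 0.7,
) -> tuple[pd.Index, pd.Index]:
    """The published ``filterByExpr`` rule; returns (kept, removed) genes.

    A gene is kept iff its CPM is at least ``min_count / median library
    size * 1e6`` in at least ``min(group sizes)`` samples (shrunk towards
    ``large_n`` by ``min_prop`` for very large groups) and its total count
    is at least ``min_total_count``.  An all-zero matrix removes every
    gene without error.
    """
    validate_matrix(counts, groups)
    if counts.shape[1] == 0 or len(counts) == 0:
        return counts.index[:0], counts.index
    group_sizes = groups.loc[counts.columns].value_counts()
    if len(group_sizes) < 2:
        raise ValidationError("base_expression_filter needs >= 2 groups")
    lib = counts.sum(axis=0).astype(float)
    median_lib = float(lib.median())
    if median_lib == 0:
        return counts.index[:0], counts.index
    min_n = float(group_sizes.min())
    if min_n > large_n:
        min_n = large_n + (min_n - large_n) * min_prop
    cpm_cutoff = min_count / median_lib * 1e6
    with np.errstate(invalid="ignore", divide="ignore"):
        cpm = counts.to_numpy(dtype=float) / lib.to_numpy() * 1e6
    cpm = np.nan_to_num(cpm, nan=0.0, posinf=0.0)
    tol = 1e-14
    keep = (cpm >= cpm_cutoff).sum(axis=1) >= min_n - tol
    keep &= counts.sum(axis=1).to_numpy() >= min_total_count - tol
    return counts.index[keep], counts.index[~keep]


# -- recovery protocol ---------------------------------------------------

@dataclass
class RecoveryResult:
    """Outcome of the group-wise recovery pass."""

    threshold: float                      # 3 x median of per-gene mean counts
    recovered: list = field(default_factory=list)
    pattern_counts: dict = field(default_factory=dict)

    @property
    def threshold_display(self) -> float:
        """The threshold as reported, rounded to 2 decimals."""
        return round(self.threshold, 2)

    @property
    def n_recovered(self) -> int:
        return len(self.recovered)


def recovery_threshold_from_median(median_mean_count: float) -> float:
    """3x the median of the per-gene mean raw counts."""
    return 3.0 * median_mean_count


def compute_recovery_threshold(counts: pd.DataFrame) -> float:
    """Recovery threshold from the full matrix (all genes, all samples)."""
    if counts.size == 0:
        raise ValidationError("cannot compute a recovery threshold on an empty matrix")
    per_gene_mean = counts.mean(axis=1)
    return recovery_threshold_from_median(float(per_gene_mean.median()))


def recover_genes(
    removed: pd.Index | list,
    counts: pd.DataFrame,
    groups: pd.Series,
    threshold: float,
) -> RecoveryResult:
    """Recover filtered-out genes whose mean raw count exceeds ``threshold``
    in exactly one or two of the three groups; report the pattern breakdown.
    """
    removed = pd.Index(removed)
    missing = removed.difference(counts.index)
    if len(missing):
        raise ValidationError(f"removed genes absent from matrix: {missing[:5].tolist()}")
    present = [g for g in GROUPS if (groups.loc[counts.columns] == g).any()]
    absent = set(GROUPS) - set(present)
    if absent:
        raise ValidationError(f"groups with zero samples: {sorted(absent)}")
    sub = counts.loc[removed]
    group_means = {
        g: sub.loc[:, groups.loc[counts.columns] == g].mean(axis=1) for g in GROUPS
    }
    above = pd.DataFrame({g: group_means[g] > threshold for g in GROUPS})
    n_above = above.sum(axis=1)
    mask = n_above.isin([1, 2])
    recovered = sorted(removed[mask])
    patterns = {}
    for gene in recovered:
        pat = "+".join(g for g in GROUPS if above.loc[gene, g])
        patterns[pat] = patterns.get(pat, 0) + 1
    return RecoveryResult(threshold=threshold, recovered=recovered, pattern_counts=patterns)


def recovery_accounting(pattern_counts: dict | list, n_base_kept: int) -> dict:
    """Totals of the recovery bookkeeping: recovered genes summed over the
    group patterns, and the gene count entering normalization (base-filter
    survivors plus recovered)."""
    values = pattern_counts.values() if isinstance(pattern_counts, dict) else pattern_counts
    n_recovered = int(sum(values))
    return {
        "n_recovered": n_recovered,
        "n_for_normalization": n_recovered + int(n_base_kept),
    }


# -- TMM normalization ---------------------------------------------------

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (Robinson-Oshlack):
    doubly trimmed, precision-weighted mean of M-values."""
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask], ref[mask]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    log_r = np.log2(p_obs / p_ref)                     # M
    abs_e = 0.5 * (np.log2(p_obs) + np.log2(p_ref))    # A
    weight = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / weight[keep]) / np.sum(1.0 / weight[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalize(
    counts: pd.DataFrame, genes: pd.Index | list | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """TMM normalization factors and the CPM matrix over ``genes``.

    Library sizes are column sums of the selected genes.  The reference
    sample is the one whose upper-quartile count (scaled by library size)
    is closest to the mean upper-quartile.  Factors are rescaled to unit
    geometric mean; CPM = count / (library size x factor) x 1e6.
    """
    sub = counts if genes is None else counts.loc[pd.Index(genes)]
    if sub.shape[1] < 2:
        raise ValidationError("TMM normalization needs >= 2 samples")
    x = sub.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        zero = sub.columns[lib == 0].tolist()
        raise ValidationError(f"samples with zero library size: {zero}")
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    cpm = x / (lib * factors) * 1e6
    return (
        pd.Series(factors, index=sub.columns, name="tmm_factor"),
        pd.DataFrame(cpm, index=sub.index, columns=sub.columns),
    )


# -- multiple testing ----------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- differential expression ---------------------------------------------

DE_METHODS = ("welch_t", "wilcoxon")


def differential_expression(
    cpm: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "Luminal",
    group_b: str = "Control",
    methods: tuple = DE_METHODS,
) -> pd.DataFrame:
    """Per-gene contrast of ``group_a`` vs ``group_b`` on log2(CPM + 0.5).

    Returns a long table (gene, log2fc, pvalue, padj, method_tag) with one
    block per configuration.  log2fc = log2(mean CPM a + 0.5) -
    log2(mean CPM b + 0.5); positive means up in ``group_a``.  p-values
    are BH-adjusted within each method.
    """
    labels = groups.loc[cpm.columns]
    a = cpm.loc[:, (labels == group_a).to_numpy()].to_numpy(dtype=float)
    b = cpm.loc[:, (labels == group_b).to_numpy()].to_numpy(dtype=float)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValidationError(f"empty contrast group in {group_a} vs {group_b}")
    log2fc = np.log2(a.mean(axis=1) + 0.5) - np.log2(b.mean(axis=1) + 0.5)
    la, lb = np.log2(a + 0.5), np.log2(b + 0.5)
    blocks = []
    for method in methods:
        if method == "welch_t":
            if a.shape[1] < 2 or b.shape[1] < 2:
                raise ValidationError(
                    "Welch t-test needs >= 2 samples per group; "
                    "use the wilcoxon configuration for singleton groups"
                )
            with warnings.catch_warnings():
                # constant genes trigger a precision warning; their p becomes 1 below
                warnings.simplefilter("ignore", RuntimeWarning)
                p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
        elif method == "wilcoxon":
            p = stats.mannwhitneyu(
                la, lb, axis=1, alternative="two-sided", method="asymptotic"
            ).pvalue
        else:
            raise ValidationError(f"unknown DE method {method!r}")
        p = np.nan_to_num(p, nan=1.0)  # constant genes: no evidence
        blocks.append(
            pd.DataFrame(
                {
                    "gene": cpm.index,
                    "log2fc": log2fc,
                    "pvalue": p,
                    "padj": bh_adjust(p),
                    "method_tag": method,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


@dataclass
class SelectionResult:
    """Genes significant under every configuration with concordant sign."""

    up: set = field(default_factory=set)
    down: set = field(default_factory=set)
    discordant: list = field(default_factory=list)

    @property
    def selected(self) -> set:
        return self.up | self.down


def select_significant(
    de: pd.DataFrame, padj_max: float = 0.001, min_abs_log2fc: float = 2.5
) -> SelectionResult:
    """Two-method consensus selection.

    A gene is selected iff it passes ``padj < padj_max`` and
    ``|log2fc| > min_abs_log2fc`` under *both* configurations with the
    same fold-change sign.  Sign-discordant genes significant in both are
    excluded and logged.
    """
    methods = sorted(de["method_tag"].unique())
    if len(methods) < 2:
        raise ValidationError("select_significant expects results from two methods")
    padj = de.pivot(index="gene", columns="method_tag", values="padj")
    lfc = de.pivot(index="gene", columns="method_tag", values="log2fc")
    if padj.isna().any().any():
        raise ValidationError("methods do not cover the same genes")
    sig = (padj < padj_max).all(axis=1) & (lfc.abs() > min_abs_log2fc).all(axis=1)
    signs = np.sign(lfc)
    concordant = signs.nunique(axis=1) == 1
    result = SelectionResult()
    for gene in padj.index[sig & ~concordant]:
        result.discordant.append(gene)
        logger.warning("select_significant: %s significant with discordant sign, excluded", gene)
    chosen = padj.index[sig & concordant]
    mean_sign = signs.loc[chosen].iloc[:, 0]
    result.up = set(chosen[mean_sign > 0])
    result.down = set(chosen[mean_sign < 0])
    return result


# -- contrast bookkeeping ------------------------------------------------

def collapse_subtypes(subtypes: pd.Series, mapping: dict) -> pd.Series:
    """Map intrinsic-subtype labels (e.g. luminal A / luminal B) onto the
    contrast groups; every label must be covered by ``mapping``."""
    collapsed = subtypes.map(mapping)
    if collapsed.isna().any():
        missing = sorted(set(subtypes[collapsed.isna()]))
        raise ValidationError(f"subtypes without group mapping: {missing}")
    return collapsed


def contrast_sizes(groups: pd.Series) -> dict:
    """Sample count per contrast group."""
    return {k: int(v) for k, v in groups.value_counts().items()}
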