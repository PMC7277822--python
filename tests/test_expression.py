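"""Expression pipeline: filter rule, recovery arithmetic, TMM, BH, DE engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lumexome import (
    SyntheticConfig,
    ValidationError,
    base_expression_filter,
    bh_adjust,
    compute_recovery_threshold,
    differential_expression,
    generate_expression_matrix,
    recover_genes,
    recovery_accounting,
    select_significant,
    tmm_normalize,
)
from lumexome.expression import collapse_subtypes, contrast_sizes


def _matrix(counts, groups):
    genes = [f"G{i}" for i in range(counts.shape[0])]
    samples = [f"S{i}" for i in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return df, pd.Series(groups, index=samples)


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(5)
    counts = rng.negative_binomial(5, 0.05, size=(100, 9))
    return _matrix(counts, ["Luminal"] * 3 + ["Others"] * 3 + ["Control"] * 3)


# -- base low-expression filter ------------------------------------------

def test_filter_extremes():
    rng = np.random.default_rng(0)
    counts = rng.poisson(200, size=(3, 6))
    counts[0] = 0          # all-zero gene goes
    counts[1] = 1000       # strongly expressed gene stays
    df, groups = _matrix(counts, ["Luminal"] * 3 + ["Control"] * 3)
    kept, removed = base_expression_filter(df, groups)
    assert "G0" in removed and "G1" in kept


def test_all_zero_matrix_removes_everything_without_error():
    df, groups = _matrix(np.zeros((4, 4), dtype=int), ["Luminal"] * 2 + ["Control"] * 2)
    kept, removed = base_expression_filter(df, groups)
    assert len(kept) == 0 and len(removed) == 4


def test_filter_matches_independent_rule_transcription(random_matrix):
    """The implementation agrees with a direct, loop-based transcription of
    the published filtering rule on a 100-gene matrix."""
    df, groups = random_matrix
    kept, _ = base_expression_filter(df, groups)

    lib = df.sum(axis=0).astype(float)
    cutoff = 10.0 / np.median(lib) * 1e6
    min_samples = min(3, 10)  # smallest group size, below the large-n regime
    expected = []
    for gene in df.index:
        cpm_row = df.loc[gene] / lib * 1e6
        if (cpm_row >= cutoff).sum() >= min_samples and df.loc[gene].sum() >= 15:
            expected.append(gene)
    assert list(kept) == expected


def test_filter_agrees_with_reference_r_implementation(random_matrix, tmp_path):
    """Cross-check filter keep-set and TMM factors against the reference
    Bioconductor implementation (edgeR) run through Rscript."""
    import subprocess

    df, groups = random_matrix
    df.to_csv(tmp_path / "counts.tsv", sep="\t")
    pd.DataFrame({"sample": df.columns, "group": groups.values}).to_csv(
        tmp_path / "groups.tsv", sep="\t", index=False
    )
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages(library(edgeR))
        args <- commandArgs(trailingOnly=TRUE)
        x <- as.matrix(read.delim(args[1], row.names=1, check.names=FALSE))
        g <- read.delim(args[2])$group
        keep <- filterByExpr(DGEList(counts=x, group=g), group=g)
        y <- calcNormFactors(DGEList(counts=x), method="TMM")
        write.table(data.frame(gene=rownames(x), keep=keep),
                    file.path(dirname(args[1]), "keep.tsv"), sep="\t", row.names=FALSE)
        write.table(data.frame(sample=colnames(x), factor=y$samples$norm.factors),
                    file.path(dirname(args[1]), "factors.tsv"), sep="\t", row.names=FALSE)
        """
    )
    subprocess.run(
        ["Rscript", str(script), str(tmp_path / "counts.tsv"), str(tmp_path / "groups.tsv")],
        check=True, capture_output=True,
    )
    r_keep = pd.read_csv(tmp_path / "keep.tsv", sep="\t")
    kept, _ = base_expression_filter(df, groups)
    assert set(kept) == set(r_keep.loc[r_keep["keep"], "gene"])
    r_factors = pd.read_csv(tmp_path / "factors.tsv", sep="\t").set_index("sample")["factor"]
    factors, _ = tmm_normalize(df)
    np.testing.assert_allclose(factors.to_numpy(), r_factors.loc[factors.index].to_numpy(),
                               rtol=1e-6)


# -- recovery threshold and recovery ------------------------------------

def test_recovery_threshold_reproduces_reported_arithmetic():
    """A matrix whose per-gene means have median 2.256 yields threshold
    6.768, displayed as 6.77."""
    counts = pd.DataFrame(
        {f"S{i}": [1, 0, 9] for i in range(125)}, index=["A", "B", "C"]
    )
    counts.loc["B"] = 0
    counts.loc["B", [f"S{i}" for i in range(282)][:125]] = 0
    # gene B: total 282 over 125 samples -> mean 2.256
    b = np.zeros(125, dtype=int)
    b[:282 % 125] = 3
    b[282 % 125:] = 2
    assert b.sum() == 282
    counts.loc["B"] = b
    threshold = compute_recovery_threshold(counts)
    assert threshold == pytest.approx(6.768)
    assert round(threshold, 2) == 6.77


def test_recovery_threshold_hand_cases():
    counts = pd.DataFrame([[1, 1], [2, 2], [9, 9]], index=list("ABC"), columns=["S1", "S2"])
    assert compute_recovery_threshold(counts) == 6.0
    zeros = pd.DataFrame(np.zeros((3, 2)), index=list("ABC"), columns=["S1", "S2"])
    assert compute_recovery_threshold(zeros) == 0.0
    with pytest.raises(ValidationError):
        compute_recovery_threshold(pd.DataFrame())


def test_recover_rule_on_constructed_group_means():
    counts = pd.DataFrame(
        {
            "L1": [10, 1, 8], "L2": [10, 1, 8],
            "O1": [1, 1, 8], "O2": [1, 1, 8],
            "C1": [1, 1, 1], "C2": [1, 1, 1],
        },
        index=["one_group", "no_group", "two_groups"],
    )
    groups = pd.Series(
        ["Luminal", "Luminal", "Others", "Others", "Control", "Control"],
        index=counts.columns,
    )
    result = recover_genes(counts.index, counts, groups, threshold=6.77)
    assert set(result.recovered) == {"one_group", "two_groups"}
    assert result.pattern_counts == {"Luminal": 1, "Luminal+Others": 1}


def test_recovery_matches_truth_and_brute_force(small_config):
    """Planted one-group genes are recovered under their pattern, and the
    recovered set equals a brute-force group-mean computation."""
    cfg = SyntheticConfig(**{**small_config.__dict__, "restricted_group_mean": 30.0})
    counts, groups, truth = generate_expression_matrix(cfg)
    kept, removed = base_expression_filter(counts, groups)
    threshold = compute_recovery_threshold(counts)
    result = recover_genes(removed, counts, groups, threshold)

    planted = set(truth.loc[truth["pattern"] == "Luminal", "gene"])
    assert planted <= set(removed)
    assert planted <= set(result.recovered)

    expected = set()
    for gene in removed:
        above = sum(
            counts.loc[gene, (groups == g).to_numpy()].mean() > threshold
            for g in ("Luminal", "Others", "Control")
        )
        if above in (1, 2):
            expected.add(gene)
    assert set(result.recovered) == expected


def test_recover_genes_invariant_to_orderings(random_matrix):
    df, groups = random_matrix
    threshold = 5.0
    removed = df.index[:50]
    base = recover_genes(removed, df, groups, threshold)
    perm = np.random.default_rng(1).permutation(df.columns)
    shuffled = recover_genes(removed[::-1], df[perm], groups, threshold)
    assert base.recovered == shuffled.recovered
    assert base.pattern_counts == shuffled.pattern_counts


def test_recovery_accounting_totals():
    patterns = {"Luminal": 159, "Control": 224, "Others": 285,
                "Others+Control": 22, "Luminal+Others": 79, "Luminal+Control": 11}
    acc = recovery_accounting(patterns, n_base_kept=26823)
    assert acc["n_recovered"] == 780
    assert acc["n_for_normalization"] == 27603


# -- TMM normalization ---------------------------------------------------

def transcribe_tmm(counts: np.ndarray) -> np.ndarray:
    """Step-by-step transcription of the trimmed-mean-of-M-values method,
    kept structurally independent of the implementation (explicit per-pair
    loops, no shared helpers)."""
    lib = counts.sum(axis=0).astype(float)
    uq = np.array([np.quantile(counts[:, j], 0.75) for j in range(counts.shape[1])]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(counts.shape[1]):
        obs, refc = counts[:, j].astype(float), counts[:, ref].astype(float)
        use = (obs > 0) & (refc > 0)
        o, r = obs[use], refc[use]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        lo_m, lo_a = int(np.floor(n * 0.3)) + 1, int(np.floor(n * 0.05)) + 1
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]) if keep.any() else 0.0
        factors.append(2.0 ** f if np.isfinite(f) else 1.0)
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_identical_samples_get_unit_factors():
    col = np.random.default_rng(2).poisson(50, size=100)
    df = pd.DataFrame({"S1": col, "S2": col, "S3": col})
    factors, cpm = tmm_normalize(df)
    np.testing.assert_allclose(factors, 1.0)
    np.testing.assert_allclose(cpm["S1"], cpm["S2"])


def test_scalar_multiple_library_gives_equal_cpm():
    """Doubling every count of one sample changes M-values nowhere, so its
    factor stays 1 and its CPM column is unchanged."""
    rng = np.random.default_rng(3)
    a = rng.poisson(100, size=200) + 1
    df = pd.DataFrame({"A": a, "B": 2 * a})
    factors, cpm = tmm_normalize(df)
    np.testing.assert_allclose(factors, 1.0, atol=1e-12)
    np.testing.assert_allclose(cpm["A"], cpm["B"])


def test_tmm_matches_independent_transcription():
    rng = np.random.default_rng(7)
    for _ in range(10):
        counts = rng.negative_binomial(3, 0.02, size=(100, 6))
        df = pd.DataFrame(counts, columns=[f"S{i}" for i in range(6)])
        factors, _ = tmm_normalize(df)
        np.testing.assert_allclose(factors.to_numpy(), transcribe_tmm(counts), atol=1e-10)


def test_tmm_scale_invariance_of_cpm():
    """Rescaling one sample's counts leaves its CPM column essentially
    unchanged.  M-values are proportion-based and exactly scale-free; the
    precision weights depend on absolute counts, so invariance is exact
    only in the proportional two-sample case and holds to ~1% otherwise."""
    rng = np.random.default_rng(9)
    counts = rng.negative_binomial(4, 0.03, size=(150, 5))
    df = pd.DataFrame(counts, columns=[f"S{i}" for i in range(5)])
    _, cpm = tmm_normalize(df)
    scaled = df.copy()
    scaled["S2"] = df["S2"] * 7
    _, cpm2 = tmm_normalize(scaled)
    np.testing.assert_allclose(cpm2["S2"], cpm["S2"], rtol=0.02)


def test_zero_library_rejected():
    df = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
    with pytest.raises(ValidationError, match="zero library"):
        tmm_normalize(df)


# -- BH adjustment -------------------------------------------------------

def closed_form_bh(p):
    """Direct step-up formula with cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_bh_hand_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.1, 1.2])
    with pytest.raises(ValidationError):
        bh_adjust([-0.1])


def test_bh_matches_closed_form_and_dominates_raw():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(1, 1001))
        p = rng.uniform(size=n)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, closed_form_bh(p), atol=1e-12)
        assert (adj >= p - 1e-12).all()


# -- differential expression and selection --------------------------------

def test_identical_groups_have_zero_log2fc():
    rng = np.random.default_rng(4)
    block = rng.uniform(1, 100, size=(20, 5))
    cpm = pd.DataFrame(np.hstack([block, block]),
                       index=[f"G{i}" for i in range(20)],
                       columns=[f"S{i}" for i in range(10)])
    groups = pd.Series(["Luminal"] * 5 + ["Control"] * 5, index=cpm.columns)
    de = differential_expression(cpm, groups)
    np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)


def test_singleton_group_suggests_rank_sum():
    cpm = pd.DataFrame({"S1": [1.0, 2.0], "S2": [2.0, 3.0], "S3": [3.0, 4.0]},
                       index=["G0", "G1"])
    groups = pd.Series(["Luminal", "Control", "Control"], index=cpm.columns)
    with pytest.raises(ValidationError, match="wilcoxon"):
        differential_expression(cpm, groups, methods=("welch_t",))


def test_selection_requires_both_methods_and_concordance():
    de = pd.DataFrame(
        {
            "gene": ["A", "A", "B", "B"],
            "log2fc": [3.0, 3.0, 3.0, 3.0],
            "pvalue": [1e-6, 1e-6, 1e-6, 0.5],
            "padj": [1e-5, 1e-5, 1e-5, 0.5],
            "method_tag": ["welch_t", "wilcoxon"] * 2,
        }
    )
    sel = select_significant(de, padj_max=0.001, min_abs_log2fc=2.5)
    assert sel.up == {"A"} and sel.down == set()  # B significant in one method only

    relaxed = select_significant(de, padj_max=1.0, min_abs_log2fc=0.0)
    assert relaxed.selected == {"A", "B"}


def test_strict_selection_nested_in_relaxed(small_expression):
    counts, groups, _ = small_expression
    _, cpm = tmm_normalize(counts)
    de = differential_expression(cpm, groups)
    strict = select_significant(de, padj_max=0.001, min_abs_log2fc=2.5)
    relaxed = select_significant(de, padj_max=0.05, min_abs_log2fc=0.0)
    assert strict.selected <= relaxed.selected


def test_planted_effects_are_recalled(small_expression):
    counts, groups, truth = small_expression
    kept, removed = base_expression_filter(counts, groups)
    rec = recover_genes(removed, counts, groups, compute_recovery_threshold(counts))
    _, cpm = tmm_normalize(counts, kept.union(pd.Index(rec.recovered)))
    de = differential_expression(cpm, groups)
    sel = select_significant(de, padj_max=0.001, min_abs_log2fc=2.5)
    planted = set(truth.loc[truth["is_de"], "gene"])
    recall = len(sel.selected & planted) / len(planted)
    assert recall >= 0.9


# -- contrast bookkeeping -------------------------------------------------

def test_luminal_contrast_sums_intrinsic_subtypes():
    subtypes = pd.Series(["LumA"] * 339 + ["LumB"] * 171 + ["Control"] * 89)
    groups = collapse_subtypes(
        subtypes, {"LumA": "Luminal", "LumB": "Luminal", "Control": "Control"}
    )
    sizes = contrast_sizes(groups)
    assert sizes == {"Luminal": 510, "Control": 89}


def test_collapse_rejects_unmapped_subtypes():
    with pytest.raises(ValidationError, match="Basal"):
        collapse_subtypes(pd.Series(["LumA", "Basal"]), {"LumA": "Luminal"})
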