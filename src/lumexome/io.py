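"""Reading, writing and validation of variant tables and driver catalogs.

The pipeline's working representation of a set of variant calls is a pandas
DataFrame with one row per (sample, site) observation and the columns listed
in :data:`VARIANT_COLUMNS`.  A *site* is identified everywhere downstream by
the key ``(build, chrom, pos, ref, alt)`` (:data:`SITE_KEY`); positions are
1-based and alleles are single nucleotides (the analysis scope is
nonsynonymous SNVs, so multi-nucleotide alleles are rejected).

Two on-disk dialects are supported:

``tsv``
    A flat tab-separated table with the fixed header of
    :data:`VARIANT_COLUMNS`.  Missing values are written as ``"."``.

``vcf``
    VCF 4.2 with the annotations carried in INFO keys (``GENE``,
    ``AACHANGE``, ``CALLERS``, ``SAMPLE`` and the six pathogenicity scores
    ``SIFT``, ``PP2``, ``MT``, ``FATHMM``, ``CADD``, ``GERP``).  A missing
    score is an absent INFO key.  Score fields are declared as String INFO
    so the decimal text round-trips exactly (htslib stores Float INFO in
    single precision).  Multi-allelic rows are split into one record per
    ALT allele on read.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Caller names recognised in the ``callers`` column.
KNOWN_CALLERS = ("GATK", "SAMtools", "FreeBayes")

#: Pathogenicity-score columns (quantitative and categorical).
SCORE_COLUMNS = ["sift", "polyphen2", "mutationtaster", "fathmm", "cadd", "gerp"]

#: Quantitative score columns used by percentile pruning.
QUANTITATIVE_SCORES = ["sift", "polyphen2", "cadd", "gerp"]

#: Columns identifying a genomic site; the identity used everywhere downstream.
SITE_KEY = ["build", "chrom", "pos", "ref", "alt"]

#: Fixed column order of the flat variant table.
VARIANT_COLUMNS = [
    "sample_id",
    "build",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "aa_change",
    "rsid",
    "callers",
    "quality",
    *SCORE_COLUMNS,
]

_MT_CATEGORIES = {"A", "D", "N", "P"}
_FATHMM_CATEGORIES = {"D", "T"}
_BASES = {"A", "C", "G", "T"}

_STRING_COLUMNS = [
    "sample_id", "build", "chrom", "ref", "alt", "gene", "aa_change",
    "rsid", "callers", "mutationtaster", "fathmm",
]
_FLOAT_COLUMNS = ["quality", "sift", "polyphen2", "cadd", "gerp"]


@dataclass(frozen=True)
class VariantRecord:
    """One allele change at one genomic site in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    sample_id: str
    aa_change: str = ""
    rsid: str = ""
    callers: frozenset[str] = field(default_factory=frozenset)
    build: str = "hg19"

    @property
    def site_key(self) -> tuple:
        return (self.build, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PathogenicityProfile:
    """The six tool scores/calls attached to a variant; any may be missing.

    Missing quantitative scores are NaN, missing categories are "".
    """

    sift: float = math.nan
    polyphen2: float = math.nan
    mutationtaster: str = ""
    fathmm: str = ""
    cadd: float = math.nan
    gerp: float = math.nan


def empty_variant_table() -> pd.DataFrame:
    """Return a variant table with the full schema and no rows."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in VARIANT_COLUMNS})
    df["pos"] = df["pos"].astype(np.int64)
    for c in _FLOAT_COLUMNS:
        df[c] = df[c].astype(float)
    for c in _STRING_COLUMNS:
        df[c] = df[c].astype(str)
    return df


def _check_scores(df: pd.DataFrame, bad: dict[int, list[str]]) -> None:
    for i, row in df.iterrows():
        problems = []
        for col, lo, hi in (("sift", 0.0, 1.0), ("polyphen2", 0.0, 1.0)):
            v = row[col]
            if not pd.isna(v) and not (lo <= v <= hi):
                problems.append(f"{col}={v} outside [{lo},{hi}]")
        if not pd.isna(row["cadd"]) and row["cadd"] < 0:
            problems.append(f"cadd={row['cadd']} negative")
        if row["mutationtaster"] and row["mutationtaster"] not in _MT_CATEGORIES:
            problems.append(f"mutationtaster={row['mutationtaster']!r}")
        if row["fathmm"] and row["fathmm"] not in _FATHMM_CATEGORIES:
            problems.append(f"fathmm={row['fathmm']!r}")
        if problems:
            bad.setdefault(i, []).extend(problems)


def validate_variants(df: pd.DataFrame, line_offset: int = 2) -> pd.DataFrame:
    """Validate a variant table against the schema invariants.

    Raises :class:`ValidationError` listing every offending row by file line
    number (``line_offset`` maps row index 0 to its line on disk; the default
    assumes a single header line).
    """
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table is missing columns: {missing}")
    df = df[VARIANT_COLUMNS].copy()
    bad: dict[int, list[str]] = {}
    for i, row in df.iterrows():
        problems = []
        if row["pos"] < 1:
            problems.append(f"pos={row['pos']} (positions are 1-based)")
        if row["ref"] == row["alt"]:
            problems.append(f"ref==alt ({row['ref']})")
        for col in ("ref", "alt"):
            if row[col] not in _BASES:
                problems.append(f"{col}={row[col]!r} is not a single nucleotide")
        if row["callers"]:
            unknown = set(row["callers"].split("|")) - set(KNOWN_CALLERS)
            if unknown:
                problems.append(f"unknown callers {sorted(unknown)}")
        if problems:
            bad.setdefault(i, []).extend(problems)
    _check_scores(df, bad)
    if bad:
        msgs = "; ".join(
            f"line {i + line_offset}: {', '.join(p)}" for i, p in sorted(bad.items())
        )
        raise ValidationError(f"invalid variant rows: {msgs}")
    return df


def site_keys(df: pd.DataFrame) -> pd.DataFrame:
    """Distinct site keys of a variant table, one row per site."""
    return df[SITE_KEY].drop_duplicates().reset_index(drop=True)


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt:
        if fmt not in {"vcf", "tsv"}:
            raise FormatError(f"unknown variant format {fmt!r} (expected vcf or tsv)")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".vcf":
        return "vcf"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise FormatError(f"cannot infer format from {path!s}; pass format explicitly")


def read_variants(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a variant table from ``path`` in the given (or inferred) format.

    Missing scores are preserved as missing (NaN / empty string), never
    imputed.  Malformed rows abort with a message listing line numbers.
    """
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        return _read_tsv(path)
    return _read_vcf(path)


def write_variants(df: pd.DataFrame, path: str | Path, format: str | None = None) -> Path:
    """Write a variant table; inverse of :func:`read_variants` field-for-field."""
    fmt = _infer_format(path, format)
    path = Path(path)
    df = df[VARIANT_COLUMNS] if len(df) else empty_variant_table()
    if fmt == "tsv":
        _write_tsv(df, path)
    else:
        _write_vcf(df, path)
    return path


# -- TSV dialect ---------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={c: str for c in _STRING_COLUMNS} | {"pos": np.int64},
            na_values=["."],
            keep_default_na=False,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as a variant TSV: {exc}") from exc
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing columns: {missing}")
    for c in _STRING_COLUMNS:
        df[c] = df[c].fillna("")
    for c in _FLOAT_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return validate_variants(df)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in _STRING_COLUMNS:
        out[c] = out[c].replace("", ".")
    for c in _FLOAT_COLUMNS:  # shortest round-trip repr; to_csv truncates digits
        out[c] = out[c].map(_fmt_float).replace("", ".")
    out.to_csv(path, sep="\t", index=False, na_rep=".")


# -- VCF dialect ---------------------------------------------------------

_VCF_INFO_KEYS = {
    "GENE": "gene",
    "AACHANGE": "aa_change",
    "CALLERS": "callers",
    "SAMPLE": "sample_id",
    "QUALITY": "quality",
    "SIFT": "sift",
    "PP2": "polyphen2",
    "MT": "mutationtaster",
    "FATHMM": "fathmm",
    "CADD": "cadd",
    "GERP": "gerp",
}

_VCF_HEADER_INFO = "\n".join(
    f'##INFO=<ID={key},Number=1,Type=String,Description="{desc}">'
    for key, desc in [
        ("GENE", "Gene symbol"),
        ("AACHANGE", "Protein change"),
        ("CALLERS", "Supporting callers, |-separated"),
        ("SAMPLE", "Sample identifier"),
        ("QUALITY", "Caller quality score (String for exact round-trip)"),
        ("SIFT", "SIFT score, damaging when low"),
        ("PP2", "PolyPhen-2 score"),
        ("MT", "MutationTaster category A/D/N/P"),
        ("FATHMM", "FATHMM category D/T"),
        ("CADD", "CADD phred-like score"),
        ("GERP", "GERP++ conservation score"),
    ]
)


def _fmt_float(v) -> str:
    return "" if pd.isna(v) else repr(float(v))


def _write_vcf(df: pd.DataFrame, path: Path) -> None:
    builds = sorted(set(df["build"])) if len(df) else []
    if len(builds) > 1:
        raise ValidationError(f"one VCF holds one genome build, got {builds}")
    lines = ["##fileformat=VCFv4.2"]
    if builds:
        lines.append(f"##build={builds[0]}")
    for chrom in sorted(set(df["chrom"]), key=str):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(_VCF_HEADER_INFO)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for _, row in df.iterrows():
        info = []
        for key, col in _VCF_INFO_KEYS.items():
            v = row[col]
            text = _fmt_float(v) if col in _FLOAT_COLUMNS else str(v)
            if text:
                info.append(f"{key}={text}")
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]),
                    str(row["pos"]),
                    row["rsid"] or ".",
                    row["ref"],
                    row["alt"],
                    _fmt_float(row["quality"]) or ".",
                    ".",
                    ";".join(info) or ".",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _read_vcf(path: str | Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on bad files
        raise FormatError(f"cannot open {path} as VCF: {exc}") from exc
    m = re.search(r"^##build=(\S+)$", vcf.raw_header, flags=re.M)
    build = m.group(1) if m else "unknown"
    rows = []
    for n, v in enumerate(vcf, start=1):
        if v.POS < 1:
            raise ValidationError(
                f"{path} record {n}: POS={v.POS} looks 0-based; VCF positions are 1-based"
            )
        info = {key: v.INFO.get(key) for key in _VCF_INFO_KEYS}
        for alt in v.ALT:  # split multi-allelic rows, one record per ALT
            rows.append(
                {
                    "sample_id": info["SAMPLE"] or "",
                    "build": build,
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alt,
                    "gene": info["GENE"] or "",
                    "aa_change": info["AACHANGE"] or "",
                    "rsid": v.ID or "",
                    "callers": info["CALLERS"] or "",
                    "quality": float(info["QUALITY"]) if info["QUALITY"] else math.nan,
                    "sift": float(info["SIFT"]) if info["SIFT"] else math.nan,
                    "polyphen2": float(info["PP2"]) if info["PP2"] else math.nan,
                    "mutationtaster": info["MT"] or "",
                    "fathmm": info["FATHMM"] or "",
                    "cadd": float(info["CADD"]) if info["CADD"] else math.nan,
                    "gerp": float(info["GERP"]) if info["GERP"] else math.nan,
                }
            )
    if not rows:
        return empty_variant_table()
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    return validate_variants(df, line_offset=0)


# -- Driver catalog ------------------------------------------------------

CATALOG_COLUMNS = ["gene", "aa_change", "status", "evidence_note"]
CATALOG_STATUSES = {"known", "reported"}


def validate_catalog(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"driver catalog is missing columns: {missing}")
    df = df[CATALOG_COLUMNS].copy()
    bad_status = sorted(set(df["status"]) - CATALOG_STATUSES)
    if bad_status:
        raise ValidationError(f"catalog status must be known/reported, got {bad_status}")
    dup = df.duplicated(subset=["gene", "aa_change"])
    if dup.any():
        keys = df.loc[dup, ["gene", "aa_change"]].apply(tuple, axis=1).tolist()
        raise ValidationError(f"duplicate catalog entries: {keys}")
    return df


def read_driver_catalog(path: str | Path) -> pd.DataFrame:
    """Read a (gene, aa_change, status, evidence_note) catalog TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    df = df.fillna("")
    return validate_catalog(df)


def write_driver_catalog(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_catalog(df).to_csv(path, sep="\t", index=False)
    return path
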