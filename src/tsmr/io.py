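"""Reading and writing GWAS summary-statistic tables and companion files.

All files are tab-delimited UTF-8 text with a header row; gzip-compressed
input is accepted transparently.  Column names vary between summary-stat
dialects, so every reader takes an optional mapping from the canonical names
(``snp``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
``pval``, ``n``) to whatever the file uses.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .datatypes import DataError, FormatError, ProxyRecord, SummaryAssociation

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "snp": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

REQUIRED = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


def read_summary_table(
    path: str | Path,
    trait_id: str,
    columns: dict[str, str] | None = None,
) -> list[SummaryAssociation]:
    """Read one trait's summary statistics into a list of records.

    Alleles are uppercased.  Rows with a non-positive standard error are
    rejected and counted in the log rather than raising, since public
    summary files routinely carry a few such rows.

    Raises
    ------
    FormatError
        If a required column is absent, naming the column.
    DataError
        If a numeric field fails to parse, naming the file line.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    for key in REQUIRED:
        if colmap[key] not in df.columns:
            raise FormatError(
                f"{path}: required column {colmap[key]!r} (for {key}) not found"
            )

    has_eaf = colmap["eaf"] in df.columns
    has_n = colmap["n"] in df.columns

    records: list[SummaryAssociation] = []
    n_rejected = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        raw = dict(zip(df.columns, row))

        def num(key: str, optional: bool = False) -> float | None:
            text = raw.get(colmap[key])
            if text is None or (isinstance(text, float) and math.isnan(text)):
                if optional:
                    return None
                raise DataError(f"{path}:{line_no}: missing value for {key}")
            try:
                return float(text)
            except ValueError:
                raise DataError(
                    f"{path}:{line_no}: cannot parse {key}={text!r} as a number"
                ) from None

        se = num("se")
        if se is None or se <= 0:
            n_rejected += 1
            continue
        records.append(
            SummaryAssociation(
                variant_id=str(raw[colmap["snp"]]),
                effect_allele=str(raw[colmap["effect_allele"]]).upper(),
                other_allele=str(raw[colmap["other_allele"]]).upper(),
                beta=num("beta"),
                se=se,
                p_value=num("pval"),
                eaf=num("eaf", optional=True) if has_eaf else None,
                n=num("n", optional=True) if has_n else None,
                trait_id=trait_id,
            )
        )
    if n_rejected:
        logger.warning(
            "%s: rejected %d row(s) with non-positive se", path, n_rejected
        )
    return records


def write_summary_table(
    records: list[SummaryAssociation], path: str | Path
) -> None:
    """Write records as a tab-delimited table using the canonical columns."""
    df = pd.DataFrame(
        {
            "snp": [r.variant_id for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.p_value for r in records],
            "n": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_proxy_table(path: str | Path) -> list[ProxyRecord]:
    """Read an LD proxy table.

    Expected columns: ``missing_variant``, ``proxy_variant``, ``r2``,
    ``missing_ea``, ``missing_oa``, ``proxy_ea``, ``proxy_oa``; the last four
    define the allele pairing between the two variants.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    needed = (
        "missing_variant",
        "proxy_variant",
        "r2",
        "missing_ea",
        "missing_oa",
        "proxy_ea",
        "proxy_oa",
    )
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} not found")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProxyRecord(
                missing_variant=row.missing_variant,
                proxy_variant=row.proxy_variant,
                r_squared=float(row.r2),
                allele_map={
                    row.missing_ea.upper(): row.proxy_ea.upper(),
                    row.missing_oa.upper(): row.proxy_oa.upper(),
                },
            )
        )
    return out


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read a variant exclusion list: one ID per line, optional tab + reason.

    Used for variants dropped on prior biological grounds, e.g. a variant in
    a blood-group locus whose pleiotropic effects violate the exclusion
    restriction.
    """
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t", 1)
        out[parts[0]] = parts[1].strip() if len(parts) > 1 else ""
    return out
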