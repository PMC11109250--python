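"""One-to-one ortholog resolution from multi-source candidate tables.

Teleost genomes carry an extra whole-genome duplication relative to
tetrapods, so a single human gene is often claimed by several query-species
co-orthologs.  Cross-species correlation needs strictly one-to-one pairs.
The resolver keeps, per human symbol, the query gene whose candidate
annotations agree across the greatest number of sources; ties are broken by
total observed UMIs, then deterministically by query-gene sort order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "SOURCE_COLUMNS",
    "OrthologTable",
    "ResolvedMap",
    "resolve_orthologs",
    "translate_genes",
]

SOURCE_COLUMNS = (
    "ncbi_gene_name",
    "ncbi_symbol",
    "ensembl_symbol",
    "protein_based_ortholog",
    "ensembl_human_ortholog",
)


@dataclass
class OrthologTable:
    """Per-query-gene human ortholog candidates from five annotation sources.

    ``table`` has one row per query gene with the five source columns
    (missing entries as NaN/empty) and a ``umi_total`` column summed over
    the supplied expression matrices.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"query_gene", "umi_total", *SOURCE_COLUMNS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
        if self.table["query_gene"].duplicated().any():
            raise ValueError("query_gene must be unique per row")
        if (self.table["umi_total"] < 0).any():
            raise ValueError("umi_total must be >= 0")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"query_gene": str}))

    def write_tsv(self, path: str | Path) -> None:
        cols = ["query_gene", *SOURCE_COLUMNS, "umi_total"]
        self.table[cols].to_csv(path, sep="\t", index=False)


@dataclass
class ResolvedMap:
    """Strictly one-to-one query-gene <-> human-symbol map."""

    pairs: pd.DataFrame  # columns: query_gene, human_symbol

    def __post_init__(self) -> None:
        if self.pairs.empty:
            self.pairs = pd.DataFrame(columns=["query_gene", "human_symbol"])
        if self.pairs["query_gene"].duplicated().any():
            raise ValueError("resolved map not one-to-one on query genes")
        if self.pairs["human_symbol"].duplicated().any():
            raise ValueError("resolved map not one-to-one on human symbols")

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "ResolvedMap":
        return cls(
            pd.DataFrame(
                {"query_gene": list(mapping), "human_symbol": list(mapping.values())}
            )
        )

    @classmethod
    def identity(cls, genes: list[str]) -> "ResolvedMap":
        """Map every gene to itself (same-species comparisons)."""
        return cls.from_dict({g: g for g in genes})

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["query_gene"], self.pairs["human_symbol"]))

    def inverse(self) -> dict[str, str]:
        return dict(zip(self.pairs["human_symbol"], self.pairs["query_gene"]))

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ResolvedMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def _consistency(row: pd.Series, symbol: str) -> int:
    """Number of the five source fields equal (case-insensitive) to ``symbol``."""
    target = symbol.casefold()
    return sum(
        1
        for col in SOURCE_COLUMNS
        if isinstance(row[col], str) and row[col].casefold() == target
    )


def resolve_orthologs(table: OrthologTable) -> ResolvedMap:
    """Resolve candidates to a one-to-one map by consistency, then UMIs.

    Per query gene the claimed human symbol is the candidate appearing in
    the greatest number of source fields (lexicographic tie-break).  Rows
    with no candidate in any source are dropped.  When several query genes
    claim the same human symbol, the one with the greatest source
    consistency is kept; ties go to the gene with the greatest ``umi_total``,
    then to query-gene sort order.  Row order of the input is irrelevant.
    """
    records = []
    for _, row in table.table.iterrows():
        candidates = {
            str(row[col]).strip()
            for col in SOURCE_COLUMNS
            if isinstance(row[col], str) and str(row[col]).strip()
        }
        if not candidates:
            continue
        scored = sorted(
            ((-_consistency(row, c), c) for c in candidates), key=lambda t: (t[0], t[1])
        )
        neg_cons, symbol = scored[0]
        records.append(
            {
                "query_gene": row["query_gene"],
                "human_symbol": symbol,
                "consistency": -neg_cons,
                "umi_total": row["umi_total"],
            }
        )
    if not records:
        return ResolvedMap(pd.DataFrame(columns=["query_gene", "human_symbol"]))
    df = pd.DataFrame(records)
    df = df.sort_values(
        ["human_symbol", "consistency", "umi_total", "query_gene"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = df.drop_duplicates("human_symbol", keep="first")
    return ResolvedMap(best[["query_gene", "human_symbol"]].reset_index(drop=True))


def translate_genes(
    genes: list[str], mapping: ResolvedMap, direction: str = "to_human"
) -> list[str]:
    """Translate gene ids through a resolved map, dropping unmapped genes.

    ``direction`` is ``"to_human"`` (query -> human symbol) or
    ``"from_human"``; input order of mapped genes is preserved.
    """
    if direction == "to_human":
        lut = mapping.to_dict()
    elif direction == "from_human":
        lut = mapping.inverse()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return [lut[g] for g in genes if g in lut]
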