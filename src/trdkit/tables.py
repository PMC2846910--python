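"""Shipped reference tables and the arithmetic checks that recompute them.

Three machine-readable fixtures travel with the package: the annotated gene
table of the bovine TRD locus (gene models with scaffold coordinates and
redundancy-group markers), the CDR feature rules defining the eleven TRDV1
phylogenetic sets, and the TRDD usage counts per V subgroup from published
junction analysis.  ``verify_gene_accounting`` and ``verify_d_usage``
recompute the headline numbers (67 TRDV1 models collapsing to 52 unique
genes, 56 unique TRDV overall; usage percentages at one decimal) from the
raw fixture data.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from trdkit.junction import d_usage_percentages
from trdkit.locus import GeneTable, collapse_redundant_models, parse_gene_table

__all__ = [
    "fixture_path",
    "load_gene_table",
    "load_set_rules",
    "load_set_members",
    "load_d_usage",
    "verify_gene_accounting",
    "verify_d_usage",
]

D_GENE_NAMES = ("TRDD1", "TRDD2", "TRDD3", "TRDD4", "TRDD5")


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped data fixture."""
    return Path(resources.files("trdkit.data") / name)


def load_gene_table() -> GeneTable:
    """The annotated TRD gene-model table (one row per gene model)."""
    with warnings.catch_warnings():
        # one J gene is printed with reversed start/end; normalization warns
        warnings.simplefilter("ignore")
        return parse_gene_table(fixture_path("table1_genes.tsv"))


def load_set_rules() -> pd.DataFrame:
    return pd.read_csv(fixture_path("table3_set_rules.tsv"), sep="\t").fillna("")


def load_set_members() -> dict[int, list[str]]:
    """Reference gene membership of the eleven TRDV1 sets."""
    df = pd.read_csv(fixture_path("table4_set_members.tsv"), sep="\t")
    return {int(r.set_id): r.members.split(",") for r in df.itertuples()}


def load_d_usage() -> pd.DataFrame:
    return pd.read_csv(fixture_path("table6_d_usage.tsv"), sep="\t").set_index(
        "subgroup"
    )


def verify_gene_accounting() -> dict[str, int]:
    """Recompute the gene counts before and after redundancy collapsing."""
    table = load_gene_table()
    collapsed = collapse_redundant_models(table)
    return {
        "trdv1_model_rows": len(table.by_subgroup("TRDV1")),
        "trdv_model_rows": len(table.by_type("V")),
        "trdv1_unique": len(collapsed.by_subgroup("TRDV1")),
        "trdv2_unique": len(collapsed.by_subgroup("TRDV2")),
        "trdv3_unique": len(collapsed.by_subgroup("TRDV3")),
        "trdv4_unique": len(collapsed.by_subgroup("TRDV4")),
        "trdv_unique": len(collapsed.by_type("V")),
        "trdd": len(collapsed.by_type("D")),
        "trdj": len(collapsed.by_type("J")),
        "trdc": len(collapsed.by_type("C")),
    }


def verify_d_usage(rounding: str = "half-up") -> pd.DataFrame:
    """Recompute usage percentages from raw counts and compare to the printed ones.

    Returns one row per (subgroup, D gene) with the raw count, the printed
    percentage, the recomputed percentage and whether they agree.  Under
    half-up rounding a single printed cell is off by 0.1 (an apparent
    truncation in the source table); all other cells agree.
    """
    usage = load_d_usage()
    rows = []
    for subgroup, rec in usage.iterrows():
        counts = {d: int(rec[f"{d}_count"]) for d in D_GENE_NAMES}
        computed = d_usage_percentages(counts, rounding=rounding)
        for d in D_GENE_NAMES:
            printed = float(rec[f"{d}_pct"])
            rows.append(
                {
                    "subgroup": subgroup,
                    "d_gene": d,
                    "count": counts[d],
                    "printed_pct": printed,
                    "computed_pct": computed[d],
                    "match": abs(computed[d] - printed) < 1e-9,
                }
            )
    return pd.DataFrame(rows)
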