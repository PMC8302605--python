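"""Over-representation analysis of gene lists against GMT gene-set collections.

Each gene set is tested for significant overlap with a query list (DEGs or a
co-expression module) under the hypergeometric model: with background size N,
set size K (after intersection with the background), query size n and overlap
k, the p-value is the upper tail P(X >= k).  BH correction is applied across
the sets tested together; when modules are tested, correction is applied
within each module's family of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term", "k", "n", "K", "N", "pvalue", "fdr", "overlap"]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from a GMT file."""

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a Gene Matrix Transposed file: name, description, members per line."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: GMT lines need >= 3 tab-separated fields "
                    "(name, description, members...)"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(query, background, sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the query list.

    Query and sets are intersected with the background universe first; query
    genes outside the background are dropped with a logged warning.  Sets with
    zero overlap are reported with p = 1.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query list")
    inside = query & background
    if not inside:
        raise ValueError("query and background share no genes")
    dropped = len(query) - len(inside)
    if dropped:
        logger.warning("dropped %d query gene(s) outside the background", dropped)
    n = len(inside)
    big_n = len(background)
    rows = []
    for term, members in sets.sets.items():
        in_bg = members & background
        big_k = len(in_bg)
        overlap = sorted(in_bg & inside)
        k = len(overlap)
        if k == 0 or big_k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({
            "term": term, "k": k, "n": n, "K": big_k, "N": big_n,
            "pvalue": min(p, 1.0), "overlap": ",".join(overlap),
        })
    out = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "fdr"])
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out[ENRICHMENT_COLUMNS]


def module_ora(
    gene_to_module: pd.Series, background, sets: GeneSetCollection
) -> pd.DataFrame:
    """Per-module ORA (module ids > 0), BH-corrected within each module."""
    frames = []
    for mod in sorted(set(gene_to_module) - {0}):
        members = list(gene_to_module.index[gene_to_module == mod])
        table = ora(members, background, sets)
        table.insert(0, "module", mod)
        frames.append(table)
    if not frames:
        raise ValueError("no modules with id > 0 to test")
    return pd.concat(frames, ignore_index=True)
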