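"""Genomic-context grouping: cluster a hit-gene list into putative operons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .synthdata import GenomeAnnotation


@dataclass(frozen=True)
class OperonGroup:
    """A run of adjacent same-strand listed genes, in genome order."""

    locus_tags: tuple[str, ...]
    scaffold: str
    strand: str
    span: int  # bp from the start of the first member to the end of the last

    def __len__(self) -> int:
        return len(self.locus_tags)


def group_operons(
    genome: GenomeAnnotation,
    gene_list: Iterable[str],
    max_gap: int = 300,
    max_intervening: int = 0,
) -> tuple[list[OperonGroup], list[str]]:
    """Merge listed genes into putative operons; return (groups, singletons).

    Two consecutive listed genes merge iff they sit on the same scaffold and
    strand, the intergenic distance between them is at most ``max_gap`` bp,
    and at most ``max_intervening`` unlisted genes lie between them. Groups
    are sorted by scaffold then start; singletons are listed genes that merge
    with nothing.
    """
    wanted = list(dict.fromkeys(gene_list))  # preserve first-seen order, dedupe
    genes = genome.genes
    known = set(genes["locus_tag"])
    unknown = [g for g in wanted if g not in known]
    if unknown:
        raise ValidationError(f"unknown locus_tags: {unknown}")
    wanted_set = set(wanted)

    ordered = genes.sort_values(["scaffold", "start"]).reset_index(drop=True)
    listed_rows = ordered[ordered["locus_tag"].isin(wanted_set)]

    runs: list[list[pd.Series]] = []
    prev = None
    prev_pos = None
    for pos, row in listed_rows.iterrows():
        if prev is not None:
            same = (
                row["scaffold"] == prev["scaffold"]
                and row["strand"] == prev["strand"]
                and (row["start"] - prev["end"] - 1) <= max_gap
                and (pos - prev_pos - 1) <= max_intervening
            )
        else:
            same = False
        if same:
            runs[-1].append(row)
        else:
            runs.append([row])
        prev, prev_pos = row, pos

    groups: list[OperonGroup] = []
    singletons: list[str] = []
    for run in runs:
        if len(run) == 1:
            singletons.append(run[0]["locus_tag"])
        else:
            groups.append(
                OperonGroup(
                    locus_tags=tuple(r["locus_tag"] for r in run),
                    scaffold=run[0]["scaffold"],
                    strand=run[0]["strand"],
                    span=int(run[-1]["end"] - run[0]["start"] + 1),
                )
            )
    return groups, singletons


def cluster_summary(
    groups: Sequence[OperonGroup], singletons: Sequence[str] = ()
) -> dict[str, int]:
    """Totals for a grouping: input size is always n_clustered + n_singletons."""
    n_clustered = sum(len(g) for g in groups)
    return {
        "n_genes": n_clustered + len(singletons),
        "n_groups": len(groups),
        "n_clustered": n_clustered,
        "n_singletons": len(singletons),
    }


def write_groups(groups: Sequence[OperonGroup], singletons: Sequence[str], path) -> None:
    rows = []
    for i, g in enumerate(groups, start=1):
        for lt in g.locus_tags:
            rows.append({"group": f"group{i}", "locus_tag": lt, "scaffold": g.scaffold,
                         "strand": g.strand, "span": g.span})
    for lt in singletons:
        rows.append({"group": "singleton", "locus_tag": lt, "scaffold": "", "strand": "", "span": ""})
    pd.DataFrame(rows, columns=["group", "locus_tag", "scaffold", "strand", "span"]).to_csv(
        path, sep="\t", index=False
    )
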