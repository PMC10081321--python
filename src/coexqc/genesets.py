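"""Gene universes and gene-set collections (GMT and two-column TSV)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class GeneUniverse:
    """A fixed, ordered gene namespace plus a term -> member-gene map.

    Every dataset is harmonized to ``genes`` before network construction so
    that co-expression matrices share an identical index.  ``term_map``
    typically holds GO terms; each term's members must be a subset of the
    universe.
    """

    genes: list[str]
    term_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("universe genes must be unique")
        gene_set = set(self.genes)
        for term, members in self.term_map.items():
            extra = set(members) - gene_set
            if extra:
                raise ValueError(
                    f"term {term!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @classmethod
    def from_term_map(cls, term_map: dict[str, list[str]]) -> "GeneUniverse":
        """Build a universe as the sorted union of all term members."""
        genes = sorted({g for members in term_map.values() for g in members})
        return cls(genes, term_map)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (term, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, members in sets.items():
            fh.write("\t".join([term, description, *members]) + "\n")


def read_term_tsv(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (term, gene) TSV into a term map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    out: dict[str, list[str]] = {}
    for term, group in df.groupby("term", sort=False):
        out[str(term)] = group["gene"].tolist()
    return out
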