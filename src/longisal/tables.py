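"""Core data containers and mothur-dialect file IO.

The analysis operates on OTU count tables produced by a mothur 16S pipeline:
a ``.shared`` file (samples x OTUs counts), a ``.cons.taxonomy`` file (one
lineage per OTU) and a per-sample metadata TSV (mouse, genotype, sex, week,
endpoint diagnosis).  :class:`OtuCountTable` bundles the three;
:class:`ClrMatrix` holds the centered log-ratio transformed view used by the
longitudinal models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

META_COLUMNS = ("mouse_id", "genotype", "sex", "week", "diagnosis")

GENOTYPES = ("WT", "KO")
SEXES = ("M", "F")
DIAGNOSES = ("ED/CIS", "OSCC")


@dataclass
class OtuCountTable:
    """Samples x OTUs integer counts with sample metadata and OTU taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, one column per OTU, nonnegative ints.
    sample_meta
        DataFrame indexed by sample id with columns
        ``mouse_id, genotype, sex, week, diagnosis``.
    taxonomy
        Series mapping OTU id -> semicolon-free lineage tuple
        (domain ... genus); ranks may be ``unclassified``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        missing = self.counts.index.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        missing_tax = self.counts.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValueError(f"OTUs without taxonomy: {list(missing_tax)[:5]}")
        # align metadata/taxonomy to the count table's ordering
        self.sample_meta = self.sample_meta.loc[self.counts.index]
        self.taxonomy = self.taxonomy.loc[self.counts.columns]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids) -> "OtuCountTable":
        return OtuCountTable(
            counts=self.counts.loc[sample_ids].copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
            taxonomy=self.taxonomy.copy(),
        )

    def copy(self) -> "OtuCountTable":
        return OtuCountTable(
            self.counts.copy(), self.sample_meta.copy(), self.taxonomy.copy()
        )


@dataclass
class ClrMatrix:
    """Samples x retained-OTUs CLR-transformed matrix.

    ``values`` rows sum to zero (up to 1e-9 * n_otus); ``replacement_record``
    stores the half-minimum value imputed for zeros in each sample (NaN when
    the sample had no zeros among retained OTUs).
    """

    values: pd.DataFrame
    retained_otus: list[str]
    replacement_record: pd.Series
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.values.shape[1]
        row_sums = self.values.values.sum(axis=1)
        if n and np.abs(row_sums).max() > 1e-9 * max(n, 1):
            raise ValueError("CLR rows must sum to zero")


# ---------------------------------------------------------------------------
# mothur-dialect readers / writers
# ---------------------------------------------------------------------------

_BOOTSTRAP_RE = re.compile(r"\(\d+\)")


def read_shared(path: str | Path) -> pd.DataFrame:
    """Read a mothur ``.shared`` file into a samples x OTUs count DataFrame.

    Columns ``label`` and ``numOtus`` are dropped; ``Group`` becomes the index.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "numOtus"):
        if col in df.columns:
            df = df.drop(columns=col)
    if "Group" not in df.columns:
        raise ValueError(f"{path}: not a mothur .shared file (no Group column)")
    df = df.set_index("Group")
    df.index.name = "sample_id"
    return df.astype(np.int64)


def write_shared(counts: pd.DataFrame, path: str | Path, label: str = "0.03") -> None:
    out = counts.copy()
    out.insert(0, "numOtus", counts.shape[1])
    out.insert(0, "Group", counts.index)
    out.insert(0, "label", label)
    out.to_csv(path, sep="\t", index=False)


def parse_lineage(raw: str) -> tuple[str, ...]:
    """Parse a mothur consensus lineage, stripping bootstrap support.

    ``Bacteria(100);Firmicutes(98);...;`` -> ("Bacteria", "Firmicutes", ...),
    padded with ``unclassified`` to six ranks.
    """
    parts = [_BOOTSTRAP_RE.sub("", p).strip().strip('"') for p in raw.strip().split(";")]
    parts = [p for p in parts if p]
    parts = parts[: len(RANKS)]
    while len(parts) < len(RANKS):
        parts.append("unclassified")
    return tuple(parts)


def read_cons_taxonomy(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    otu_col = cols.get("otu", df.columns[0])
    tax_col = cols.get("taxonomy", df.columns[-1])
    lineages = df[tax_col].map(parse_lineage)
    return pd.Series(lineages.values, index=df[otu_col].values, name="taxonomy")


def write_cons_taxonomy(
    taxonomy: pd.Series, sizes: pd.Series | None, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("OTU\tSize\tTaxonomy\n")
        for otu, lineage in taxonomy.items():
            size = int(sizes[otu]) if sizes is not None else 0
            fh.write(f"{otu}\t{size}\t{';'.join(lineage)};\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mouse_id": str})
    meta = meta.set_index("sample_id")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata missing column {col!r}")
    meta["week"] = meta["week"].astype(int)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_table(
    shared: str | Path, taxonomy: str | Path, metadata: str | Path
) -> OtuCountTable:
    """Assemble an :class:`OtuCountTable` from the three mothur-side files."""
    counts = read_shared(shared)
    tax = read_cons_taxonomy(taxonomy)
    meta = read_metadata(metadata)
    return OtuCountTable(counts=counts, sample_meta=meta, taxonomy=tax)
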