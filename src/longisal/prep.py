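"""Compositional preprocessing: prevalence filtering, zero replacement,
centered log-ratio transform, rarefaction and taxonomy aggregation.

The CLR pipeline used by the longitudinal models is::

    prevalence filter (strictly-below threshold removed)
      -> per-sample half-minimum zero replacement on the retained submatrix
      -> log(x) - mean(log x) per sample

Rarefaction (used by the diversity / theta_YC analyses) subsamples each
sample without replacement to a fixed depth, dropping shallower samples.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import RANKS, ClrMatrix, OtuCountTable



def replace_zeros_half_min(row: np.ndarray) -> np.ndarray:
    """Replace zeros with half the smallest nonzero value of the row.

    Raises ``ValueError`` on an all-zero row (the replacement is undefined).
    """
    row = np.asarray(row, dtype=float)
    nonzero = row[row > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero row: half-minimum replacement undefined")
    out = row.copy()
    out[out == 0] = nonzero.min() / 2.0
    return out


def prevalence(table: OtuCountTable, otu: str | None = None):
    """Fraction of samples in which an OTU has count > 0.

    With ``otu=None`` returns the full per-OTU prevalence Series.
    """
    prev = (table.counts > 0).mean(axis=0)
    if otu is None:
        return prev
    if otu not in prev.index:
        raise KeyError(f"unknown OTU {otu!r}")
    return float(prev[otu])


def filter_prevalence(table: OtuCountTable, prevalence_min: float) -> list[str]:
    """OTU ids retained by a strict 'prevalence below threshold removed' rule.

    An OTU at exactly the threshold is retained.
    """
    if not 0 <= prevalence_min < 1:
        raise ValueError("prevalence_min must be in [0, 1)")
    prev = prevalence(table)
    return list(prev.index[prev >= prevalence_min])


def clr_transform(table: OtuCountTable, prevalence_min: float = 0.05) -> ClrMatrix:
    """Prevalence-filter, zero-replace and CLR-transform a count table.

    Samples that are all-zero on the retained OTU set are dropped with a
    warning and listed in ``ClrMatrix.dropped_samples``.
    """
    retained = filter_prevalence(table, prevalence_min)
    if not retained:
        raise ValueError("no OTUs retained by the prevalence filter")
    sub = table.counts[retained].astype(float)

    totals = sub.values.sum(axis=1)
    degenerate = sub.index[totals == 0]
    if len(degenerate):
        warnings.warn(
            f"{len(degenerate)} sample(s) all-zero after the prevalence filter; "
            f"dropped: {list(degenerate)[:5]}"
        )
        sub = sub.drop(index=degenerate)

    values = np.empty(sub.shape)
    replacement = np.full(sub.shape[0], np.nan)
    mat = sub.values
    for i in range(mat.shape[0]):
        row = mat[i]
        if (row == 0).any():
            replacement[i] = row[row > 0].min() / 2.0
        filled = replace_zeros_half_min(row)
        logs = np.log(filled)
        values[i] = logs - logs.mean()

    return ClrMatrix(
        values=pd.DataFrame(values, index=sub.index, columns=retained),
        retained_otus=retained,
        replacement_record=pd.Series(replacement, index=sub.index),
        dropped_samples=list(degenerate),
    )


def rarefy(table: OtuCountTable, depth: int, seed: int) -> OtuCountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped.  The draw is a
    multivariate hypergeometric per sample, a single seeded draw (no
    averaging over repeated subsamples).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals.index[totals >= depth]
    if len(keep) == 0:
        warnings.warn("all samples below rarefaction depth; empty table returned")
    rows = []
    for sid in keep:
        row = table.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(keep), table.n_otus),
        index=keep,
        columns=table.counts.columns,
    )
    return OtuCountTable(
        counts=counts,
        sample_meta=table.sample_meta.loc[keep].copy(),
        taxonomy=table.taxonomy.copy(),
    )


def aggregate_taxonomy(table: OtuCountTable, rank: str) -> OtuCountTable:
    """Sum counts over OTUs sharing the lineage prefix up to ``rank``.

    OTUs unclassified at ``rank`` are pooled under ``unclassified_<parent>``
    where parent is the deepest classified rank of their lineage.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    depth = RANKS.index(rank)

    labels = {}
    for otu, lineage in table.taxonomy.items():
        name = lineage[depth]
        if name.startswith("unclassified") or name == "":
            classified = [p for p in lineage[:depth] if not p.startswith("unclassified")]
            parent = classified[-1] if classified else "root"
            name = f"unclassified_{parent}"
        labels[otu] = name

    groups = pd.Series(labels)
    counts = table.counts.T.groupby(groups).sum().T
    # taxon lineage for an aggregate: prefix up to rank, padded
    lineages = {}
    for otu, lineage in table.taxonomy.items():
        lab = groups[otu]
        if lab not in lineages:
            pref = list(lineage[: depth + 1])
            while len(pref) < len(RANKS):
                pref.append("unclassified")
            lineages[lab] = tuple(pref)
    taxonomy = pd.Series({lab: lineages[lab] for lab in counts.columns})
    return OtuCountTable(
        counts=counts, sample_meta=table.sample_meta.copy(), taxonomy=taxonomy
    )


def write_clr(clr: ClrMatrix, directory: str | Path, stem: str = "clr") -> dict:
    """Write CLR matrix TSV, retained-OTU list TSV and a filter report JSON."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    clr_path = directory / f"{stem}_matrix.tsv"
    clr.values.rename_axis("sample_id").to_csv(clr_path, sep="\t")
    otus_path = directory / f"{stem}_retained_otus.tsv"
    pd.Series(clr.retained_otus, name="otu").to_csv(otus_path, sep="\t", index=False)
    report = {
        "n_retained_otus": len(clr.retained_otus),
        "n_samples": int(clr.values.shape[0]),
        "dropped_samples": clr.dropped_samples,
    }
    report_path = directory / f"{stem}_filter_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    return {"clr": clr_path, "otus": otus_path, "report": report_path}
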