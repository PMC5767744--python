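"""Transcript abundance normalization (RPKM) and expression filtering."""

from __future__ import annotations

import pandas as pd

from .io import GeneOrder, validate_expression


def rpkm(count: float, cds_length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million aligned reads.

    count / ((cds_length/1000) * (total_mapped/1e6)).
    """
    if cds_length <= 0:
        raise ValueError("cds_length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return count / ((cds_length / 1_000) * (total_mapped / 1_000_000))


def rpkm_matrix(counts: pd.DataFrame, gene_order: GeneOrder,
                total_mapped: pd.Series | None = None) -> pd.DataFrame:
    """Normalize a model x accession read-count matrix to RPKM.

    The per-accession denominator defaults to the column sum, i.e. all reads
    aligned anywhere on the reference.
    """
    lengths = gene_order.frame.set_index("model")["cds_length"]
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise KeyError(f"models missing from gene order: {sorted(missing)[:5]}")
    if total_mapped is None:
        total_mapped = counts.sum(axis=0)
    total_mapped = total_mapped.reindex(counts.columns)
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be > 0 for every accession")
    kb = lengths.reindex(counts.index).to_numpy() / 1_000
    millions = total_mapped.to_numpy() / 1_000_000
    out = counts.div(kb, axis=0).div(millions, axis=1)
    return validate_expression(out)


def expression_filter(matrix: pd.DataFrame, min_mean: float = 0.4) -> pd.Index:
    """Model ids with panel-mean RPKM strictly above ``min_mean``.

    The mean is taken over every accession in the panel, zeros included.
    """
    if matrix.empty:
        return matrix.index[:0]
    return matrix.index[matrix.mean(axis=1) > min_mean]
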