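"""SNP identification from per-accession transcriptome pileups.

In an allopolyploid, reads from the two homoeologous subgenomes cross-map,
so a site can show a fixed mixture of two bases within a single inbred
accession. Such states are scored with two-base IUPAC codes and the
resulting polymorphisms are "hemi-SNPs"; polymorphisms between resolved
single bases are "simple SNPs". Calling proceeds per accession and site:
a read-depth floor, then a noise threshold on per-base frequencies; sites
are then filtered panel-wide on missingness, allele count and polymorphism,
classified, genome-assigned and annotated with minor-allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    BASES,
    IUPAC2,
    IUPAC2_BASES,
    MISSING,
    GeneOrder,
    SiteCallMatrix,
    split_site_id,
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Lookup from the bitmask of bases above the noise threshold to a call state.
# Bit i set <=> base BASES[i] passes. One base -> that base; two bases -> the
# IUPAC code; zero or three-plus -> missing (a three-base mixture is not
# representable in the two-base alphabet).
_MASK_TO_STATE = np.full(16, MISSING, dtype="U1")
for _b, _i in _BASE_INDEX.items():
    _MASK_TO_STATE[1 << _i] = _b
for _pair, _code in IUPAC2.items():
    _mask = 0
    for _b in _pair:
        _mask |= 1 << _BASE_INDEX[_b]
    _MASK_TO_STATE[_mask] = _code


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the SNP-identification rules.

    min_depth_exclusive: calls require read depth strictly in excess of this
        (default 10, i.e. depth >= 11).
    noise_freq: a base contributes to the call only at frequency >= this
        fraction of quality-passing reads (default 0.2); ambiguity codes are
        emitted only when exactly two bases pass.
    max_missing_frac: sites with a missing-call fraction at or above this are
        excluded (default 0.25).
    max_alleles: maximum number of distinct non-missing call states at a
        retained site (default 3, e.g. A / G / R).
    maf_min_exclusive: association and LD analyses keep markers with minor
        allele frequency strictly above this (default 0.01).
    """

    min_depth_exclusive: int = 10
    noise_freq: float = 0.2
    max_missing_frac: float = 0.25
    max_alleles: int = 3
    maf_min_exclusive: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.noise_freq < 0.5:
            raise ValueError("noise_freq must lie in (0, 0.5)")
        if not 0 < self.max_missing_frac < 1:
            raise ValueError("max_missing_frac must lie in (0, 1)")
        if self.max_alleles < 2:
            raise ValueError("max_alleles must be >= 2")


def call_base(counts, depth: int, params: CallingParams | None = None) -> str:
    """Call one accession at one site from quality-passing base counts.

    Returns a resolved base, a two-base IUPAC code, or ``N``.
    """
    params = params or CallingParams()
    bad = set(counts) - set(BASES)
    if bad:
        raise ValueError(f"unknown base keys: {sorted(bad)}")
    if depth <= params.min_depth_exclusive:
        return MISSING
    total = sum(counts.values())
    if total == 0:
        return MISSING
    passing = [b for b in BASES if counts.get(b, 0) / total >= params.noise_freq]
    if len(passing) == 1:
        return passing[0]
    if len(passing) == 2:
        return IUPAC2[frozenset(passing)]
    return MISSING


def call_bases_array(counts: np.ndarray, depth: np.ndarray,
                     params: CallingParams | None = None) -> np.ndarray:
    """Vectorized :func:`call_base` over a ``(..., 4)`` count array."""
    params = params or CallingParams()
    counts = np.asarray(counts)
    depth = np.asarray(depth)
    total = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / np.where(total == 0, 1, total)[..., None]
    passing = freq >= params.noise_freq
    mask = (passing << np.arange(4)).sum(axis=-1)
    states = _MASK_TO_STATE[mask]
    states = np.where((depth <= params.min_depth_exclusive) | (total == 0),
                      MISSING, states)
    return states.astype("U1")


def build_site_calls(pileup: pd.DataFrame,
                     params: CallingParams | None = None) -> SiteCallMatrix:
    """Pivot a pileup table into an accession x site call matrix.

    Accession/site pairs absent from the pileup are missing calls. Output
    accession and site order is sorted, so permuting pileup rows never
    changes the result.
    """
    params = params or CallingParams()
    site_id = pileup["model"].astype(str) + ":" + pileup["position"].astype(str)
    accessions = sorted(pileup["accession"].unique())
    sites = sorted(site_id.unique())
    acc_idx = pd.Categorical(pileup["accession"], categories=accessions).codes
    site_idx = pd.Categorical(site_id, categories=sites).codes

    counts = np.zeros((len(accessions), len(sites), 4), dtype=np.int64)
    depth = np.zeros((len(accessions), len(sites)), dtype=np.int64)
    for k, base in enumerate(BASES):
        counts[acc_idx, site_idx, k] = pileup[base].to_numpy()
    depth[acc_idx, site_idx] = pileup["depth"].to_numpy()

    calls = call_bases_array(counts, depth, params)
    return SiteCallMatrix(calls, accessions, sites)


def filter_sites(matrix: SiteCallMatrix,
                 params: CallingParams | None = None,
                 return_log: bool = False):
    """Apply the panel-wide site filters.

    A site is retained when its missing fraction is below
    ``max_missing_frac``, it shows at most ``max_alleles`` distinct
    non-missing states, and it is polymorphic (>= 2 states).
    """
    params = params or CallingParams()
    calls = matrix.calls
    n_acc = matrix.n_accessions
    missing = calls == MISSING
    missing_frac = missing.mean(axis=0)

    n_states = np.zeros(matrix.n_sites, dtype=int)
    for state in sorted(set(np.unique(calls)) - {MISSING}):
        n_states += (calls == state).any(axis=0)

    ok_missing = missing_frac < params.max_missing_frac
    ok_alleles = n_states <= params.max_alleles
    ok_poly = n_states >= 2
    keep = ok_missing & ok_alleles & ok_poly

    out = SiteCallMatrix(
        calls[:, keep], matrix.accession_ids,
        [s for s, k in zip(matrix.site_ids, keep) if k],
    )
    if return_log:
        log = {
            "n_candidate_sites": matrix.n_sites,
            "excluded_missingness": int((~ok_missing).sum()),
            "excluded_allele_count": int((ok_missing & ~ok_alleles).sum()),
            "excluded_monomorphic": int((ok_missing & ok_alleles & ~ok_poly).sum()),
            "n_retained": int(keep.sum()),
        }
        return out, log
    return out


def _state_counts(column: np.ndarray) -> dict[str, int]:
    states, counts = np.unique(column[column != MISSING], return_counts=True)
    return dict(zip(states.tolist(), counts.tolist()))


def classify_snp(column: np.ndarray) -> str:
    """``hemi`` when any observed state is an ambiguity code, else ``simple``."""
    counts = _state_counts(column)
    if len(counts) < 2:
        raise ValueError("monomorphic site cannot be classified")
    return "hemi" if any(s in IUPAC2_BASES for s in counts) else "simple"


def assign_genome(site_id: str, snp_class: str, gene_order: GeneOrder,
                  linkage_evidence: set[str]) -> bool:
    """Can the marker be placed on its host model's subgenome with confidence?

    Simple SNPs always can; hemi-SNPs only when mapped directly in the
    doubled-haploid linkage population (the polymorphism may otherwise sit in
    either homoeologue of the model in which it was scored).
    """
    model, _ = split_site_id(site_id)
    if model not in gene_order:
        raise KeyError(f"model {model!r} not in gene order")
    if snp_class == "simple":
        return True
    return site_id in linkage_evidence


def compute_maf(column: np.ndarray) -> float:
    """Frequency of the second most frequent call state among non-missing calls."""
    counts = _state_counts(column)
    if not counts:
        raise ValueError("all calls missing")
    if len(counts) < 2:
        raise ValueError("monomorphic site has no minor allele")
    total = sum(counts.values())
    second = sorted(counts.values(), reverse=True)[1]
    return second / total


def annotate_markers(matrix: SiteCallMatrix, gene_order: GeneOrder,
                     linkage_evidence: set[str] | None = None) -> pd.DataFrame:
    """Per-site class, genome assignability, MAF and plotting position."""
    linkage_evidence = linkage_evidence or set()
    records = []
    for site_id in matrix.site_ids:
        column = matrix.site(site_id)
        snp_class = classify_snp(column)
        model, _ = split_site_id(site_id)
        rec = gene_order.record(model)
        records.append({
            "site_id": site_id,
            "model": model,
            "snp_class": snp_class,
            "genome_assigned": assign_genome(site_id, snp_class, gene_order,
                                             linkage_evidence),
            "maf": compute_maf(column),
            "chromosome": rec["chromosome"],
            "order_index": int(rec["order_index"]),
        })
    return pd.DataFrame(
        records, columns=["site_id", "model", "snp_class", "genome_assigned",
                          "maf", "chromosome", "order_index"],
    )


def call_snps(pileup: pd.DataFrame, gene_order: GeneOrder,
              linkage_evidence: set[str] | None = None,
              params: CallingParams | None = None):
    """Full pipeline: pileup -> filtered call matrix + marker annotations.

    Returns ``(matrix, annotations, log)`` where ``log`` records per-filter
    exclusion counts.
    """
    params = params or CallingParams()
    raw = build_site_calls(pileup, params)
    matrix, log = filter_sites(raw, params, return_log=True)
    annotations = annotate_markers(matrix, gene_order, linkage_evidence)
    log["n_simple"] = int((annotations["snp_class"] == "simple").sum())
    log["n_hemi"] = int((annotations["snp_class"] == "hemi").sum())
    log["n_genome_assigned"] = int(annotations["genome_assigned"].sum())
    log["n_maf_gt_min"] = int(
        (annotations["maf"] > params.maf_min_exclusive).sum()
    )
    return matrix, annotations, log
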