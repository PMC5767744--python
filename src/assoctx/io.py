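"""Readers, writers and validated containers for the platform's file formats.

All tabular files are UTF-8 and tab-delimited except trait tables, which are
CSV. Sites are addressed as ``model:position`` with 1-based positions in
transcript (CDS-model) coordinates; plotting positions are the pair
(chromosome, order index of the gene model), not base pairs. Missing calls
are serialized as ``N``; hemi-SNP states use two-base IUPAC ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Brassica napus chromosome names in plotting order (A genome then C genome).
CHROMOSOMES = [f"A{i}" for i in range(1, 11)] + [f"C{i}" for i in range(1, 10)]

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

BASES = ("A", "C", "G", "T")

#: Two-base IUPAC ambiguity codes, the only hemi-SNP states serialized.
IUPAC2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
IUPAC2_BASES = {code: pair for pair, code in IUPAC2.items()}

MISSING = "N"

VALID_STATES = frozenset(BASES) | frozenset(IUPAC2.values()) | {MISSING}


def chrom_rank(chromosome: str) -> int:
    """Plotting rank of a chromosome (A1..A10 precede C1..C9)."""
    try:
        return _CHROM_RANK[chromosome]
    except KeyError:
        raise ValueError(f"unknown chromosome {chromosome!r}") from None


def is_ambiguous(state: str) -> bool:
    return state in IUPAC2_BASES


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------

@dataclass
class GeneOrder:
    """Ordered CDS gene models of the pan-transcriptome reference.

    ``frame`` columns: model, chromosome, order_index, cds_length, genome,
    and optionally homoeologue (the paired model on the other subgenome,
    empty string when unpaired).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"model", "chromosome", "order_index", "cds_length"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"gene order missing columns: {sorted(missing_cols)}")
        if df["model"].duplicated().any():
            dup = df.loc[df["model"].duplicated(), "model"].iloc[0]
            raise ValueError(f"duplicate model id {dup!r}")
        bad = ~df["chromosome"].isin(CHROMOSOMES)
        if bad.any():
            raise ValueError(
                f"unknown chromosome {df.loc[bad, 'chromosome'].iloc[0]!r}"
            )
        if (df["cds_length"] < 3).any():
            raise ValueError("cds_length must be >= 3")
        if "genome" not in df.columns:
            df = df.assign(genome=df["chromosome"].str[0])
        elif (df["genome"] != df["chromosome"].str[0]).any():
            raise ValueError("genome inconsistent with chromosome prefix")
        if "homoeologue" not in df.columns:
            df = df.assign(homoeologue="")
        df = df.copy()
        df["order_index"] = df["order_index"].astype(int)
        for chrom, sub in df.groupby("chromosome"):
            oi = sub["order_index"].to_numpy()
            if len(oi) > 1 and not (np.diff(np.sort(oi)) > 0).all():
                raise ValueError(f"order_index not strictly increasing on {chrom}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))
        object.__setattr__(
            self, "_by_model", df.set_index("model", drop=False)
        )

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, model: str) -> bool:
        return model in self._by_model.index

    def record(self, model: str) -> pd.Series:
        try:
            return self._by_model.loc[model]
        except KeyError:
            raise KeyError(f"model {model!r} not in gene order") from None

    def chromosome_of(self, model: str) -> str:
        return str(self.record(model)["chromosome"])

    def genome_of(self, model: str) -> str:
        return str(self.record(model)["genome"])

    def homoeologue_of(self, model: str) -> str | None:
        h = str(self.record(model)["homoeologue"])
        return h or None

    def sorted(self) -> "GeneOrder":
        df = self.frame.copy()
        df["_rank"] = df["chromosome"].map(_CHROM_RANK)
        df = df.sort_values(["_rank", "order_index"]).drop(columns="_rank")
        return GeneOrder(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Site-call matrix
# ---------------------------------------------------------------------------

class SiteCallMatrix:
    """Accession x site matrix of base-call states.

    States are resolved bases, two-base IUPAC codes (hemi-SNP mixtures) or
    ``N`` for missing. Stored sites-in-columns: ``calls[i, j]`` is the state
    of accession i at site j.
    """

    def __init__(self, calls: np.ndarray, accession_ids, site_ids):
        calls = np.asarray(calls, dtype="U1")
        accession_ids = list(accession_ids)
        site_ids = list(site_ids)
        if calls.shape != (len(accession_ids), len(site_ids)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(accession_ids)} accessions x {len(site_ids)} sites"
            )
        observed = set(np.unique(calls))
        bad = observed - VALID_STATES
        if bad:
            raise ValueError(f"invalid call states: {sorted(bad)}")
        self.calls = calls
        self.accession_ids = accession_ids
        self.site_ids = site_ids
        self._acc_index = {a: i for i, a in enumerate(accession_ids)}
        self._site_index = {s: j for j, s in enumerate(site_ids)}

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site(self, site_id: str) -> np.ndarray:
        return self.calls[:, self._site_index[site_id]]

    def accession(self, accession_id: str) -> np.ndarray:
        return self.calls[self._acc_index[accession_id], :]

    def select_sites(self, site_ids) -> "SiteCallMatrix":
        idx = [self._site_index[s] for s in site_ids]
        return SiteCallMatrix(self.calls[:, idx], self.accession_ids, list(site_ids))

    def select_accessions(self, accession_ids) -> "SiteCallMatrix":
        idx = [self._acc_index[a] for a in accession_ids]
        return SiteCallMatrix(self.calls[idx, :], list(accession_ids), self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        """Sites-as-rows frame (site_id index, accession columns)."""
        return pd.DataFrame(
            self.calls.T, index=pd.Index(self.site_ids, name="site_id"),
            columns=self.accession_ids,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SiteCallMatrix)
            and self.accession_ids == other.accession_ids
            and self.site_ids == other.site_ids
            and bool((self.calls == other.calls).all())
        )


def split_site_id(site_id: str) -> tuple[str, int]:
    """Split ``model:position`` into its parts."""
    model, _, pos = site_id.rpartition(":")
    if not model:
        raise ValueError(f"malformed site id {site_id!r}")
    return model, int(pos)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["accession", "model", "position", "depth", "A", "C", "G", "T"]


def validate_pileup(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup missing columns: {sorted(missing)}")
    for col in ("position", "depth", "A", "C", "G", "T"):
        vals = df[col].to_numpy()
        if col == "position":
            if (vals < 1).any():
                line = int(np.argmax(vals < 1)) + 2
                raise ValueError(f"line {line}: position must be >= 1")
        elif (vals < 0).any():
            line = int(np.argmax(vals < 0)) + 2
            raise ValueError(f"line {line}: negative {col}")
    count_sum = df[["A", "C", "G", "T"]].sum(axis=1).to_numpy()
    over = count_sum > df["depth"].to_numpy()
    if over.any():
        line = int(np.argmax(over)) + 2
        raise ValueError(f"line {line}: base counts exceed depth")
    return df[PILEUP_COLUMNS]


def read_pileup(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t",
            dtype={"accession": str, "model": str, "position": np.int64,
                   "depth": np.int64, "A": np.int64, "C": np.int64,
                   "G": np.int64, "T": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed pileup file {path}: {exc}") from exc
    return validate_pileup(df)


def write_pileup(df: pd.DataFrame, path) -> None:
    validate_pileup(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene order I/O
# ---------------------------------------------------------------------------

def read_gene_order(path) -> GeneOrder:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"model": str, "chromosome": str, "order_index": np.int64,
               "cds_length": np.int64, "genome": str, "homoeologue": str},
        keep_default_na=False,
    )
    return GeneOrder(df)


def write_gene_order(order: GeneOrder, path) -> None:
    order.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site-call matrix I/O
# ---------------------------------------------------------------------------

def read_site_calls(path) -> SiteCallMatrix:
    df = pd.read_csv(path, sep="\t", index_col="site_id", dtype=str,
                     keep_default_na=False)
    return SiteCallMatrix(df.to_numpy(dtype="U1").T,
                          list(df.columns), list(df.index))


def write_site_calls(matrix: SiteCallMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Expression matrices (models x accessions, RPKM)
# ---------------------------------------------------------------------------

def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    if (vals < 0).any():
        raise ValueError("RPKM values must be non-negative")
    return df


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="model")
    return validate_expression(df)


def write_expression(df: pd.DataFrame, path) -> None:
    validate_expression(df)
    out = df.copy()
    out.index.name = "model"
    out.to_csv(path, sep="\t", float_format="%.4f")


# ---------------------------------------------------------------------------
# Trait tables (CSV; empty field = missing)
# ---------------------------------------------------------------------------

def read_trait(path) -> pd.Series:
    df = pd.read_csv(path, dtype={"accession": str})
    if "accession" not in df.columns or df.shape[1] != 2:
        raise ValueError("trait file must have columns: accession, <trait>")
    trait_col = [c for c in df.columns if c != "accession"][0]
    if df["accession"].duplicated().any():
        raise ValueError("duplicate accession in trait file")
    s = pd.Series(df[trait_col].to_numpy(dtype=float),
                  index=df["accession"], name=trait_col)
    return s.dropna()


def write_trait(trait: pd.Series, path, name: str | None = None) -> None:
    name = name or trait.name or "trait"
    df = pd.DataFrame({"accession": trait.index, name: trait.to_numpy()})
    df.to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Association scans
# ---------------------------------------------------------------------------

SCAN_COLUMNS = ["id", "chromosome", "order_index", "minus_log10_p",
                "effect", "assigned", "lambda_gc"]


def _check_scan_sorted(df: pd.DataFrame) -> None:
    ranks = df["chromosome"].map(_CHROM_RANK).to_numpy()
    oi = df["order_index"].to_numpy()
    key = ranks * (oi.max() + 1 if len(oi) else 1) + oi
    if len(key) > 1 and (np.diff(key) < 0).any():
        raise ValueError("scan must be sorted by (chromosome, order_index)")


def validate_scan(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scan missing columns: {sorted(missing)}")
    if (df["minus_log10_p"] < 0).any():
        raise ValueError("minus_log10_p must be >= 0")
    if (df["lambda_gc"] <= 0).any():
        raise ValueError("lambda_gc must be > 0")
    return df


def read_scan(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chromosome": str})
    df["assigned"] = df["assigned"].astype(bool)
    validate_scan(df)
    _check_scan_sorted(df)
    return df[SCAN_COLUMNS]


def write_scan(df: pd.DataFrame, path) -> None:
    validate_scan(df)
    _check_scan_sorted(df)
    out = df[SCAN_COLUMNS].copy()
    for col in ("minus_log10_p", "effect", "lambda_gc"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["site_id", "model", "snp_class", "genome_assigned",
                      "maf", "chromosome", "order_index"]


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotations missing columns: {sorted(missing)}")
    if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        raise ValueError("maf must lie in [0, 0.5]")
    bad = ~df["snp_class"].isin(["simple", "hemi"])
    if bad.any():
        raise ValueError("snp_class must be 'simple' or 'hemi'")
    return df


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"site_id": str, "model": str, "chromosome": str})
    df["genome_assigned"] = df["genome_assigned"].astype(bool)
    return validate_annotations(df)[ANNOTATION_COLUMNS]


def write_annotations(df: pd.DataFrame, path) -> None:
    validate_annotations(df)
    out = df[ANNOTATION_COLUMNS].copy()
    out["maf"] = out["maf"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Linkage evidence: site ids mapped in a doubled-haploid linkage population
# ---------------------------------------------------------------------------

def read_linkage_evidence(path) -> set[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "site_id" not in df.columns:
        raise ValueError("linkage evidence file must have a site_id column")
    return set(df["site_id"])


def write_linkage_evidence(site_ids, path) -> None:
    pd.DataFrame({"site_id": sorted(site_ids)}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic numeric matrix I/O (Q, kinship, dosage) and newick output
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def write_newick(newick: str, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def read_newick(path) -> str:
    with open(path, encoding="utf-8") as fh:
        return fh.read().strip()
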