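"""Trait association: mixed-model SNP scans and expression-marker (GEM) scans.

Two model classes follow the fit-then-results convention:

``SNPAssociation``
    y = X b + m_j a_j + g + e per marker, with X = [1, Q] fixed covariates,
    g ~ N(0, sigma_g^2 K) random polygenic effect. The null variance
    structure is fitted once by REML and reused across markers (P3D).
    The null fit's sigma_g^2 / (sigma_g^2 + sigma_e^2) is the SNP-based
    narrow-sense heritability estimate.

``GEMAssociation``
    Fixed-effect regression of the trait on each gene's transcript
    abundance (RPKM) with the Q-matrix as covariates; genomic control
    deflates the p-value scan when the inflation factor lambda exceeds 1.

Significance thresholds: Bonferroni at the number of markers actually
tested, and the Benjamini-Hochberg 5% false-discovery-rate line used for
plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneOrder, chrom_rank, split_site_id
from .mlm import NullMLM, _partial_regression, exact_scan, fit_null_mlm, gls_scan
from .quantify import expression_filter
from .structure import EncodedGenotypes

#: Median of the chi-square(1) distribution, the genomic-control null median.
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))


# ---------------------------------------------------------------------------
# Thresholds and genomic control
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """-log10 of the Bonferroni-corrected per-test significance level."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return float(-np.log10(alpha / m_tests))


def fdr_line(p_values, q: float = 0.05) -> float:
    """-log10 of the Benjamini-Hochberg cutoff (inf when nothing passes)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    order = np.sort(p)
    crit = q * np.arange(1, p.size + 1) / p.size
    passing = np.nonzero(order <= crit)[0]
    if passing.size == 0:
        return float("inf")
    return float(-np.log10(order[passing[-1]]))


def genomic_control(p_values) -> tuple[float, np.ndarray]:
    """Genomic-control inflation factor and the adjusted p-values.

    lambda = median(chi2_1 quantiles of p) / median of chi2_1. When
    lambda > 1 every chi-square is divided by lambda and the p-values are
    recomputed; otherwise they are returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / CHI2_NULL_MEDIAN)
    if lam > 1:
        adjusted = stats.chi2.sf(chi / lam, 1)
        return lam, np.clip(adjusted, np.finfo(float).tiny, 1.0)
    return lam, p.copy()


# ---------------------------------------------------------------------------
# Manhattan tables
# ---------------------------------------------------------------------------

def manhattan_table(scan: pd.DataFrame, gene_order: GeneOrder) -> pd.DataFrame:
    """Plot-ready table ordered A1..A10 then C1..C9 by gene-model order.

    ``scan`` needs columns id, model, minus_log10_p, assigned. Assigned
    markers appear once as dark points at their host model's position;
    unassigned markers are pale and, when the host model has a homoeologue,
    are duplicated at both homoeologous positions (the polymorphism may
    belong to either copy, so the unassigned signal casts a homoeologous
    shadow).
    """
    rows = []
    for rec in scan.itertuples(index=False):
        model = rec.model
        if model not in gene_order:
            raise KeyError(f"model {model!r} not in gene order")
        host = gene_order.record(model)
        placements = [(str(host["chromosome"]), int(host["order_index"]))]
        if not rec.assigned:
            partner = gene_order.homoeologue_of(model)
            if partner is not None and partner in gene_order:
                p_rec = gene_order.record(partner)
                placements.append(
                    (str(p_rec["chromosome"]), int(p_rec["order_index"]))
                )
        for chrom, oi in placements:
            rows.append({
                "id": rec.id, "chromosome": chrom, "order_index": oi,
                "minus_log10_p": rec.minus_log10_p,
                "dark": bool(rec.assigned),
            })
    out = pd.DataFrame(rows, columns=["id", "chromosome", "order_index",
                                      "minus_log10_p", "dark"])
    out["_rank"] = out["chromosome"].map(chrom_rank)
    out = out.sort_values(["_rank", "order_index", "id"]).drop(columns="_rank")
    out.insert(0, "x_rank", np.arange(1, len(out) + 1))
    return out.reset_index(drop=True)


def plot_manhattan(table: pd.DataFrame, threshold: float | None = None,
                   fdr: float | None = None, ax=None):
    """Minimal Manhattan rendering: dark/pale points, threshold lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for dark, grp in table.groupby("dark"):
        ax.scatter(grp["x_rank"], grp["minus_log10_p"], s=4,
                   color="0.2" if dark else "0.75",
                   label="assigned" if dark else "unassigned")
    if threshold is not None and np.isfinite(threshold):
        ax.axhline(threshold, color="lightblue", ls="--", lw=1)
    if fdr is not None and np.isfinite(fdr):
        ax.axhline(fdr, color="darkblue", ls="--", lw=1)
    ax.set_xlabel("gene-model order")
    ax.set_ylabel(r"$-\log_{10} P$")
    return ax


# ---------------------------------------------------------------------------
# Alignment helpers
# ---------------------------------------------------------------------------

def _align(trait: pd.Series, accession_ids: list[str]):
    trait = trait.dropna()
    keep = [a for a in accession_ids if a in trait.index]
    if len(keep) < 3:
        raise ValueError("fewer than 3 accessions shared between trait and data")
    return keep, trait.loc[keep].to_numpy(dtype=float)


def _covariates(n: int, Q: pd.DataFrame | None, keep: list[str]) -> np.ndarray:
    X = np.ones((n, 1))
    if Q is not None:
        q = Q.loc[keep].to_numpy(dtype=float)
        # admixture rows sum to 1: drop one column to keep X full rank
        X = np.column_stack([X, q[:, :-1]])
    return X


# ---------------------------------------------------------------------------
# SNP association
# ---------------------------------------------------------------------------

class SNPAssociation:
    """Mixed-linear-model association of trait with SNP dosages.

    Parameters
    ----------
    trait : pd.Series indexed by accession (missing accessions are dropped).
    genotypes : EncodedGenotypes.
    annotations : marker annotation frame (site_id, snp_class,
        genome_assigned, maf, chromosome, order_index); markers are filtered
        to MAF above ``maf_min`` before testing.
    Q : admixture-proportion matrix or None.
    K : kinship matrix or None (None = identity, i.e. plain fixed-effects).
    """

    def __init__(self, trait: pd.Series, genotypes: EncodedGenotypes,
                 annotations: pd.DataFrame | None = None,
                 Q: pd.DataFrame | None = None,
                 K: pd.DataFrame | None = None,
                 maf_min: float = 0.01):
        self.trait = trait
        self.genotypes = genotypes
        self.annotations = annotations
        self.Q = Q
        self.K = K
        self.maf_min = maf_min

    def fit(self, p3d: bool = True, alpha: float = 0.05,
            apply_gc: bool = False) -> "SNPAssociationResults":
        keep, y = _align(self.trait, self.genotypes.accession_ids)
        geno = self.genotypes.select_accessions(keep)

        ann = self.annotations
        if ann is not None:
            ann = ann.set_index("site_id").reindex(geno.site_ids)
            tested = ann.index[ann["maf"] > self.maf_min].tolist()
        else:
            tested = list(geno.site_ids)
        geno = geno.select_sites(tested)

        X = _covariates(len(keep), self.Q, keep)
        if self.K is not None:
            K = self.K.loc[keep, keep].to_numpy(dtype=float)
        else:
            K = np.eye(len(keep))
        null = fit_null_mlm(y, X, K)
        markers = geno.dosages
        if p3d:
            effect, se, tval, pval = gls_scan(null, markers)
        else:
            effect, se, tval, pval = exact_scan(y, X, K, markers)

        lam_gc = 1.0
        if apply_gc:
            ok = np.isfinite(pval)
            lam_gc, adj = genomic_control(pval[ok])
            pval = pval.copy()
            pval[ok] = adj

        scan = pd.DataFrame({
            "id": tested,
            "model": [split_site_id(s)[0] for s in tested],
            "effect": effect, "se": se, "p": pval,
            "minus_log10_p": -np.log10(np.clip(pval, np.finfo(float).tiny, 1)),
        })
        if ann is not None:
            sub = ann.loc[tested]
            scan["maf"] = sub["maf"].to_numpy()
            scan["assigned"] = sub["genome_assigned"].to_numpy()
            scan["chromosome"] = sub["chromosome"].to_numpy()
            scan["order_index"] = sub["order_index"].to_numpy()
        else:
            scan["maf"] = np.nan
            scan["assigned"] = True
        return SNPAssociationResults(
            model=self, scan=scan, null=null, alpha=alpha, lambda_gc=lam_gc,
            accessions=keep,
        )


@dataclass
class SNPAssociationResults:
    model: SNPAssociation
    scan: pd.DataFrame
    null: NullMLM
    alpha: float
    lambda_gc: float
    accessions: list[str]

    @property
    def h2(self) -> float:
        """SNP-based narrow-sense (pseudo-)heritability."""
        return self.null.h2

    @property
    def varcomp(self):
        return self.null.varcomp

    @property
    def n_tested(self) -> int:
        return int(np.isfinite(self.scan["p"]).sum())

    @property
    def bonferroni(self) -> float:
        return bonferroni_threshold(self.alpha, max(self.n_tested, 1))

    @property
    def fdr(self) -> float:
        p = self.scan["p"].to_numpy()
        return fdr_line(p[np.isfinite(p)])

    def significant(self) -> pd.DataFrame:
        return self.scan[self.scan["minus_log10_p"] > self.bonferroni]

    def manhattan_table(self, gene_order: GeneOrder) -> pd.DataFrame:
        return manhattan_table(self.scan, gene_order)

    def plot_manhattan(self, gene_order: GeneOrder, ax=None):
        return plot_manhattan(self.manhattan_table(gene_order),
                              self.bonferroni, self.fdr, ax=ax)

    def to_scan_frame(self) -> pd.DataFrame:
        """Serializable scan table sorted by (chromosome, order index)."""
        df = self.scan.copy()
        if "chromosome" not in df or df["chromosome"].isna().any():
            raise ValueError("scan lacks chromosome annotations")
        df["lambda_gc"] = self.lambda_gc
        df = df.rename(columns={"effect": "effect"})
        df["_rank"] = df["chromosome"].map(chrom_rank)
        df = df.sort_values(["_rank", "order_index", "id"]).drop(columns="_rank")
        return df[["id", "chromosome", "order_index", "minus_log10_p",
                   "effect", "assigned", "lambda_gc"]].reset_index(drop=True)

    def summary(self) -> str:
        top = self.scan.nlargest(5, "minus_log10_p")
        lines = [
            "SNP association (mixed linear model, P3D)",
            "=" * 48,
            f"accessions: {len(self.accessions)}   markers tested: {self.n_tested}",
            f"sigma_g^2: {self.varcomp.sigma_g2:.4f}   "
            f"sigma_e^2: {self.varcomp.sigma_e2:.4f}   h^2: {self.h2:.3f}",
            f"lambda_gc: {self.lambda_gc:.3f}",
            f"Bonferroni (-log10 P at alpha={self.alpha}): {self.bonferroni:.2f}",
            f"markers above Bonferroni: {len(self.significant())}",
            "",
            "top markers:",
        ]
        for rec in top.itertuples(index=False):
            lines.append(
                f"  {rec.id:<24} -log10P={rec.minus_log10_p:7.2f}"
                f"  effect={rec.effect: .4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# GEM association
# ---------------------------------------------------------------------------

class GEMAssociation:
    """Fixed-effect regression of trait on per-gene transcript abundance.

    Genes are pre-filtered to panel-mean RPKM above ``min_mean``. Each
    retained gene is tested by OLS of trait on (RPKM, Q columns, intercept);
    the reported slope is the structure-adjusted RPKM coefficient and the
    intercept anchors the prediction line at the panel means, so
    ``intercept + slope * RPKM`` predicts the trait of a new accession.
    """

    def __init__(self, trait: pd.Series, expression: pd.DataFrame,
                 Q: pd.DataFrame | None = None, min_mean: float = 0.4):
        self.trait = trait
        self.expression = expression
        self.Q = Q
        self.min_mean = min_mean

    def fit(self, apply_gc: bool = True, alpha: float = 0.05
            ) -> "GEMAssociationResults":
        keep, y = _align(self.trait, list(self.expression.columns))
        expr = self.expression[keep]
        models = expression_filter(expr, self.min_mean)
        expr = expr.loc[models]
        X = _covariates(len(keep), self.Q, keep)

        M = expr.to_numpy(dtype=float).T  # accessions x models
        ok_var = M.std(axis=0) > 0
        beta, se, tval, pval, df = _partial_regression(y, X, M)
        beta[~ok_var] = np.nan
        pval[~ok_var] = np.nan

        # full-model R^2 per gene
        Qr, _ = np.linalg.qr(X)
        y_res = y - Qr @ (Qr.T @ y)
        M_res = M - Qr @ (Qr.T @ M)
        mm = np.einsum("ij,ij->j", M_res, M_res)
        rss_cov = float(y_res @ y_res)
        with np.errstate(invalid="ignore"):
            rss_full = rss_cov - np.where(mm > 0, beta ** 2 * mm, 0.0)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = np.clip(1.0 - rss_full / tss, 0.0, 1.0)

        xbar = M.mean(axis=0)
        intercept = y.mean() - beta * xbar

        lam = 1.0
        p_adj = pval.copy()
        if apply_gc:
            ok = np.isfinite(pval)
            if ok.any():
                lam, adj = genomic_control(pval[ok])
                p_adj[ok] = adj

        fits = pd.DataFrame({
            "model": list(models),
            "slope": beta, "intercept": intercept, "r2": r2,
            "p": pval, "p_adjusted": p_adj,
            "minus_log10_p": -np.log10(np.clip(p_adj, np.finfo(float).tiny, 1)),
        }).dropna(subset=["p"]).reset_index(drop=True)
        return GEMAssociationResults(model=self, fits=fits, lambda_gc=lam,
                                     alpha=alpha, accessions=keep)


@dataclass
class GEMAssociationResults:
    model: GEMAssociation
    fits: pd.DataFrame
    lambda_gc: float
    alpha: float
    accessions: list[str]

    @property
    def n_tested(self) -> int:
        return len(self.fits)

    @property
    def bonferroni(self) -> float:
        return bonferroni_threshold(self.alpha, max(self.n_tested, 1))

    @property
    def fdr(self) -> float:
        return fdr_line(self.fits["p_adjusted"].to_numpy())

    def significant(self) -> pd.DataFrame:
        return self.fits[self.fits["minus_log10_p"] > self.bonferroni]

    def manhattan_table(self, gene_order: GeneOrder) -> pd.DataFrame:
        scan = self.fits.rename(columns={"model": "id"}).copy()
        scan["model"] = scan["id"]
        scan["assigned"] = True
        return manhattan_table(scan, gene_order)

    def plot_manhattan(self, gene_order: GeneOrder, ax=None):
        return plot_manhattan(self.manhattan_table(gene_order),
                              self.bonferroni, self.fdr, ax=ax)

    def summary(self) -> str:
        top = self.fits.nlargest(5, "minus_log10_p")
        lines = [
            "GEM association (fixed-effect model with Q covariates)",
            "=" * 54,
            f"accessions: {len(self.accessions)}   genes tested: {self.n_tested}",
            f"lambda_gc: {self.lambda_gc:.3f} "
            f"({'adjusted' if self.lambda_gc > 1 else 'no adjustment'})",
            f"Bonferroni (-log10 P at alpha={self.alpha}): {self.bonferroni:.2f}",
            f"genes above Bonferroni: {len(self.significant())}",
            "",
            "top gene expression markers:",
        ]
        for rec in top.itertuples(index=False):
            lines.append(
                f"  {rec.model:<24} -log10P={rec.minus_log10_p:7.2f}"
                f"  slope={rec.slope: .4f}  r2={rec.r2:.3f}"
            )
        return "\n".join(lines)
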