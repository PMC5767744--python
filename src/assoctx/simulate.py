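"""Synthetic allopolyploid diversity-panel generator.

Emulates the statistical structure the platform assumes: an inbred
(doubled-haploid) panel of 383 accessions with k = 2 admixed
subpopulations, two homoeologous subgenomes (A and C) whose paired gene
models cross-map at a configurable rate (the hemi-SNP mechanism), two
major-effect biallelic seed loci on chromosomes A8 and C3, and one causal
gene on C2 whose transcript abundance, not sequence, drives the trait
through a negative slope. Subpopulation allele frequencies follow a
Balding-Nichols drift model. All stages are deterministic under a seed and
all ground truth is returned for recovery tests.

Sequence-level features of real panels that are NOT simulated: linkage
disequilibrium decay along chromosomes (sites are exchangeable given
structure), homoeologous exchange and copy-number variation, and read-level
quality variation (counts are emitted post quality filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import BASES, CHROMOSOMES, GeneOrder

_A_CHROMS = [c for c in CHROMOSOMES if c.startswith("A")]
_C_CHROMS = [c for c in CHROMOSOMES if c.startswith("C")]


@dataclass
class PanelConfig:
    """Study conditions of the default simulated panel."""

    n_accessions: int = 383
    n_models_per_genome: int = 150
    sites_per_model: int = 3
    k: int = 2
    fst: float = 0.1
    admixed_frac: float = 0.2
    depth_mean: float = 50.0
    error_rate: float = 0.005
    cross_mapping_rate: float = 0.3
    cross_mapping_model_frac: float = 0.7
    homoeologue_divergence: float = 0.7
    linkage_mapped_frac: float = 0.3
    snp_loci: tuple = (("A8", 0.30), ("C3", 0.20))
    expression_frac: float = 0.15
    expression_slope_sign: int = -1
    causal_chromosome: str = "C2"
    silent_frac: float = 0.15
    log_rpkm_mean: float = 1.5
    log_rpkm_sd: float = 0.8
    h2: float = 0.65
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.cross_mapping_rate <= 0.5:
            raise ValueError("cross_mapping_rate must lie in [0, 0.5]")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must lie in (0, 1]")


@dataclass
class PanelTruth:
    """Ground truth persisted alongside the fixtures."""

    admixture: np.ndarray
    subpop_labels: np.ndarray
    subpop_freqs: np.ndarray
    causal_sites: list = field(default_factory=list)   # (site_id, effect, frac)
    causal_model: str | None = None
    expression_slope: float = 0.0
    expression_frac: float = 0.0
    snp_variance_fraction: float = 0.0
    h2_target: float = 0.0
    h2_realized: float = 0.0
    cross_mapping_rate: float = 0.0
    seed: int = 0

    def to_jsonable(self) -> dict:
        return {
            "causal_sites": [(s, float(e), float(f))
                             for s, e, f in self.causal_sites],
            "causal_model": self.causal_model,
            "expression_slope": float(self.expression_slope),
            "expression_frac": float(self.expression_frac),
            "snp_variance_fraction": float(self.snp_variance_fraction),
            "h2_target": float(self.h2_target),
            "h2_realized": float(self.h2_realized),
            "cross_mapping_rate": float(self.cross_mapping_rate),
            "seed": int(self.seed),
        }


# ---------------------------------------------------------------------------
# Genotypes and panel structure
# ---------------------------------------------------------------------------

def _make_gene_order(config: PanelConfig, rng: np.random.Generator) -> GeneOrder:
    rows = []
    n = config.n_models_per_genome
    for genome, chroms in (("A", _A_CHROMS), ("C", _C_CHROMS)):
        chrom_of = [chroms[i % len(chroms)] for i in range(n)]
        counters: dict[str, int] = {}
        for i in range(n):
            chrom = chrom_of[i]
            counters[chrom] = counters.get(chrom, 0) + 1
            partner = f"m{'C' if genome == 'A' else 'A'}{i:04d}"
            rows.append({
                "model": f"m{genome}{i:04d}",
                "chromosome": chrom,
                "order_index": counters[chrom],
                "cds_length": int(rng.integers(300, 3001)),
                "genome": genome,
                "homoeologue": partner,
            })
    return GeneOrder(pd.DataFrame(rows))


def simulate_genotypes(config: PanelConfig, rng: np.random.Generator):
    """Balding-Nichols genotypes on a paired two-genome gene order.

    Returns (gene_order, sites, genotypes, admixture, labels, subpop_freqs).
    ``sites`` has one row per polymorphic site: site_id, model, position,
    ref, alt, homoeo_base; ``genotypes`` is accessions x sites in {0, 1}
    (alternate-allele carrier; the panel is inbred so calls are homozygous).
    """
    order = _make_gene_order(config, rng)
    n_sites = 2 * config.n_models_per_genome * config.sites_per_model
    n, k = config.n_accessions, config.k

    # ancestral frequencies and per-subpopulation drift
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    if config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        freqs = rng.beta(a, b, size=(k, n_sites))
    else:
        freqs = np.tile(p_anc, (k, 1))

    # admixture: mostly unadmixed accessions plus a Dirichlet-admixed tail
    labels = np.arange(n) % k
    admix = np.zeros((n, k))
    admix[np.arange(n), labels] = 1.0
    n_adm = int(round(config.admixed_frac * n))
    if n_adm:
        idx = rng.choice(n, size=n_adm, replace=False)
        admix[idx] = rng.dirichlet(np.ones(k), size=n_adm)
        labels = admix.argmax(axis=1)

    acc_freq = admix @ freqs
    geno = (rng.random((n, n_sites)) < acc_freq).astype(np.uint8)

    # site table: base identities, the base cross-mapping in from the
    # homoeologous position (homoeologues taken as fixed at that position),
    # and the per-site cross-mapping rate. Cross-mapping is a property of
    # the model pair: for a fraction of pairs read mapping cannot separate
    # the homoeologues and those models cross-map at the configured rate;
    # reads of the remaining models map discriminately (rate 0), which is
    # what yields simple SNPs.
    sites = []
    base_idx = rng.integers(0, 4, size=n_sites)
    alt_off = rng.integers(1, 4, size=n_sites)
    divergent = rng.random(n_sites) < config.homoeologue_divergence
    homoeo_off = rng.integers(1, 4, size=n_sites)
    models = order.frame["model"].tolist()
    pair_crosses = rng.random(config.n_models_per_genome) < \
        config.cross_mapping_model_frac
    pos_counter = 0
    for mi, model in enumerate(models):
        length = int(order.record(model)["cds_length"])
        pair_index = mi % config.n_models_per_genome
        rate = config.cross_mapping_rate if pair_crosses[pair_index] else 0.0
        positions = np.sort(
            rng.choice(np.arange(1, length + 1),
                       size=min(config.sites_per_model, length), replace=False)
        )
        for pos in positions:
            j = pos_counter
            ref = BASES[base_idx[j]]
            alt = BASES[(base_idx[j] + alt_off[j]) % 4]
            if divergent[j]:
                homoeo = BASES[(base_idx[j] + homoeo_off[j]) % 4]
            else:
                homoeo = ref
            sites.append({
                "site_id": f"{model}:{pos}", "model": model,
                "position": int(pos), "ref": ref, "alt": alt,
                "homoeo_base": homoeo, "cross_rate": rate,
            })
            pos_counter += 1
    sites = pd.DataFrame(sites)
    geno = geno[:, : len(sites)]
    return order, sites, geno, admix, labels, freqs


# ---------------------------------------------------------------------------
# Pileups (the hemi-SNP mechanism)
# ---------------------------------------------------------------------------

def simulate_pileups(sites: pd.DataFrame, geno: np.ndarray,
                     accession_ids: list[str], config: PanelConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Poisson-depth base counts with homoeologous cross-mapping.

    A ``cross_mapping_rate`` fraction of each site's reads carries the
    homoeologous base; sequencing errors move reads uniformly onto the
    other three bases. Counts are post quality filtering by construction.
    """
    n, m = geno.shape
    base_of = {b: i for i, b in enumerate(BASES)}
    ref = np.array([base_of[b] for b in sites["ref"]])
    alt = np.array([base_of[b] for b in sites["alt"]])
    homoeo = np.array([base_of[b] for b in sites["homoeo_base"]])

    own = np.where(geno == 1, alt[None, :], ref[None, :])   # n x m base index
    if "cross_rate" in sites.columns:
        c = sites["cross_rate"].to_numpy()[None, :]
    else:
        c = np.full((1, m), config.cross_mapping_rate)
    e = config.error_rate

    q = np.zeros((n, m, 4))
    np.put_along_axis(q, own[..., None], 1.0, axis=2)
    q *= (1.0 - c)[..., None]
    homoeo_tiled = np.broadcast_to(homoeo[None, :], (n, m))
    np.add.at(q, (np.arange(n)[:, None], np.arange(m)[None, :], homoeo_tiled),
              np.broadcast_to(c, (n, m)))
    p = q * (1 - e) + (1 - q) * (e / 3.0)

    depth = rng.poisson(config.depth_mean, size=(n, m))
    counts = rng.multinomial(depth, p)

    acc_col = np.repeat(accession_ids, m)
    out = pd.DataFrame({
        "accession": acc_col,
        "model": np.tile(sites["model"].to_numpy(), n),
        "position": np.tile(sites["position"].to_numpy(), n),
        "depth": depth.ravel(),
        "A": counts[:, :, 0].ravel(),
        "C": counts[:, :, 1].ravel(),
        "G": counts[:, :, 2].ravel(),
        "T": counts[:, :, 3].ravel(),
    })
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(order: GeneOrder, admix: np.ndarray,
                        accession_ids: list[str], config: PanelConfig,
                        rng: np.random.Generator):
    """Log-normal background RPKM with one expression-variant causal gene.

    The causal gene carries a biallelic expression variant whose frequency
    differs between subpopulations, producing a bimodal, structure-
    correlated abundance profile. A ``silent_frac`` of genes is near-silent
    to exercise the expression filter. Returns (expression frame
    [models x accessions], causal_model, causal_rpkm, expression_allele).
    """
    models = order.frame["model"].tolist()
    n = len(accession_ids)
    m = len(models)
    log_mu = rng.normal(config.log_rpkm_mean, 0.5, size=m)
    silent = rng.random(m) < config.silent_frac
    log_mu[silent] = np.log(0.02)
    rpkm = np.exp(log_mu[:, None]
                  + rng.normal(0.0, config.log_rpkm_sd, size=(m, n)))

    candidates = [mo for mo in models
                  if order.chromosome_of(mo) == config.causal_chromosome]
    causal_model = candidates[rng.integers(len(candidates))]
    ci = models.index(causal_model)

    k = admix.shape[1]
    allele_freq = np.linspace(0.85, 0.15, k)
    p_high = admix @ allele_freq
    expr_allele = (rng.random(n) < p_high).astype(np.uint8)  # 1 = high state
    log_levels = np.where(expr_allele == 1, np.log(12.0), np.log(2.0))
    causal_rpkm = np.exp(log_levels + rng.normal(0.0, 0.3, size=n))
    rpkm[ci] = causal_rpkm

    expr = pd.DataFrame(rpkm, index=pd.Index(models, name="model"),
                        columns=accession_ids)
    return expr, causal_model, causal_rpkm, expr_allele


# ---------------------------------------------------------------------------
# Trait
# ---------------------------------------------------------------------------

def _pick_causal_site(sites: pd.DataFrame, geno: np.ndarray, order: GeneOrder,
                      chromosome: str, rng: np.random.Generator) -> int:
    chrom_of = sites["model"].map(
        order.frame.set_index("model")["chromosome"]
    ).to_numpy()
    freq = geno.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    # prefer sites in discriminately-mapped (non-cross-mapping) models, which
    # will be scored as genome-assignable simple SNPs
    if "cross_rate" in sites.columns:
        clean = sites["cross_rate"].to_numpy() == 0
    else:
        clean = np.ones(len(sites), dtype=bool)
    for require_clean in (True, False):
        for lo, hi in ((0.2, 0.45), (0.1, 0.5), (0.01, 0.5)):
            ok = (chrom_of == chromosome) & (maf >= lo) & (maf <= hi)
            if require_clean:
                ok &= clean
            ok = np.nonzero(ok)[0]
            if ok.size:
                return int(ok[rng.integers(ok.size)])
    raise ValueError(f"no polymorphic site available on {chromosome}")


def simulate_trait(sites: pd.DataFrame, geno: np.ndarray, order: GeneOrder,
                   causal_rpkm: np.ndarray, accession_ids: list[str],
                   config: PanelConfig, rng: np.random.Generator):
    """Trait from major loci plus an expression-mediated component.

    Effects are scaled so each configured locus contributes its variance
    fraction (in trait-variance units); the residual variance is matched to
    the realized genetic variance so the realized heritability equals the
    target. Returns (trait Series, causal site list, slope, h2_realized).
    """
    n = len(accession_ids)
    g = np.zeros(n)
    causal = []
    for chrom, frac in config.snp_loci:
        j = _pick_causal_site(sites, geno, order, chrom, rng)
        x = geno[:, j].astype(float)
        v = x.var()
        if v == 0:
            raise ValueError("degenerate causal genotype")
        beta = np.sqrt(frac / v)
        g += beta * x
        causal.append((sites.iloc[j]["site_id"], float(beta), float(frac)))

    slope = 0.0
    if config.expression_frac > 0:
        v = causal_rpkm.var()
        if v == 0:
            raise ValueError("degenerate causal expression")
        slope = config.expression_slope_sign * np.sqrt(config.expression_frac / v)
        g = g + slope * causal_rpkm

    var_g = g.var()
    if var_g == 0:
        raise ValueError("degenerate genetic variance")
    if config.h2 >= 1:
        noise = np.zeros(n)
    else:
        sigma_e = np.sqrt(var_g * (1 - config.h2) / config.h2)
        noise = rng.normal(0.0, sigma_e, size=n)
    y = g + noise
    tot = np.var(g) + np.var(noise)
    h2_realized = float(np.var(g) / tot) if tot > 0 else 1.0
    trait = pd.Series(y, index=accession_ids, name="trait")
    return trait, causal, float(slope), h2_realized


# ---------------------------------------------------------------------------
# Whole-panel composition
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    config: PanelConfig
    gene_order: GeneOrder
    sites: pd.DataFrame
    genotypes: np.ndarray
    accession_ids: list[str]
    pileup: pd.DataFrame
    expression: pd.DataFrame
    trait: pd.Series
    linkage_evidence: set[str]
    truth: PanelTruth


def simulate_panel(config: PanelConfig | None = None,
                   seed: int | None = None) -> SyntheticPanel:
    """Generate a complete panel: pileups, expression, trait and truth."""
    config = config or PanelConfig()
    if seed is not None:
        config = PanelConfig(**{**asdict(config), "seed": seed})
    rng = np.random.default_rng(config.seed)
    accession_ids = [f"acc{i:04d}" for i in range(config.n_accessions)]

    order, sites, geno, admix, labels, freqs = simulate_genotypes(config, rng)
    pileup = simulate_pileups(sites, geno, accession_ids, config, rng)
    expr, causal_model, causal_rpkm, expr_allele = simulate_expression(
        order, admix, accession_ids, config, rng)
    trait, causal_sites, slope, h2_real = simulate_trait(
        sites, geno, order, causal_rpkm, accession_ids, config, rng)

    n_linked = int(round(config.linkage_mapped_frac * len(sites)))
    linked = rng.choice(sites["site_id"].to_numpy(), size=n_linked,
                        replace=False)
    truth = PanelTruth(
        admixture=admix, subpop_labels=labels, subpop_freqs=freqs,
        causal_sites=causal_sites, causal_model=causal_model,
        expression_slope=slope, expression_frac=config.expression_frac,
        snp_variance_fraction=float(sum(f for _, f in config.snp_loci)),
        h2_target=config.h2, h2_realized=h2_real,
        cross_mapping_rate=config.cross_mapping_rate, seed=config.seed,
    )
    return SyntheticPanel(
        config=config, gene_order=order, sites=sites, genotypes=geno,
        accession_ids=accession_ids, pileup=pileup, expression=expr,
        trait=trait, linkage_evidence=set(linked), truth=truth,
    )
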