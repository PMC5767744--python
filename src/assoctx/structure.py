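"""Relatedness, population structure and linkage disequilibrium.

The panel is inbred/doubled-haploid, so every call state at a marker is one
fixed allele; markers are bridged to statistics through an alternate-state
dosage in [0, 1]. Relatedness is summarized two ways: a Jukes-Cantor (JC69)
distance matrix over the call sequences (for the dendrogram) and a
standardized-dosage kinship matrix (the random-effect covariance of the
mixed model). The Q-matrix is a PCA-to-simplex admixture surrogate: top
principal coordinates, cluster archetypes, and a least-squares projection of
every accession onto the simplex those archetypes span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import IUPAC2_BASES, MISSING, SiteCallMatrix


# ---------------------------------------------------------------------------
# Dosage encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodedGenotypes:
    """Accession x marker dosage matrix with a per-marker state legend.

    ``dosages[i, j]`` in [0, 1] or NaN for missing. ``legend[j]`` maps every
    non-missing state observed at marker j to its dosage.
    """

    dosages: np.ndarray
    accession_ids: list[str]
    site_ids: list[str]
    legend: list[dict[str, float]]

    def __post_init__(self) -> None:
        d = self.dosages
        finite = d[np.isfinite(d)]
        if finite.size and ((finite < 0) | (finite > 1)).any():
            raise ValueError("dosages must lie in [0, 1]")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.site_ids)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.accession_ids,
                            columns=self.site_ids)

    def select_sites(self, site_ids) -> "EncodedGenotypes":
        pos = {s: j for j, s in enumerate(self.site_ids)}
        idx = [pos[s] for s in site_ids]
        return EncodedGenotypes(self.dosages[:, idx], self.accession_ids,
                                list(site_ids), [self.legend[j] for j in idx])

    def select_accessions(self, accession_ids) -> "EncodedGenotypes":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = [pos[a] for a in accession_ids]
        return EncodedGenotypes(self.dosages[idx, :], list(accession_ids),
                                self.site_ids, self.legend)


def _encode_column(column: np.ndarray) -> dict[str, float]:
    states, counts = np.unique(column[column != MISSING], return_counts=True)
    if len(states) > 3:
        raise ValueError("more than 3 states; site should have been filtered")
    # deterministic: order by descending count, ties lexicographic
    order = sorted(zip(states.tolist(), counts.tolist()),
                   key=lambda t: (-t[1], t[0]))
    ranked = [s for s, _ in order]
    if len(ranked) == 1:
        return {ranked[0]: 0.0}
    if len(ranked) == 2:
        return {ranked[0]: 0.0, ranked[1]: 1.0}
    # three states: if one is the IUPAC union of the other two, it is the
    # mixed (hemi) state and sits at the dosage midpoint
    for cand in ranked:
        rest = [s for s in ranked if s != cand]
        if cand in IUPAC2_BASES and IUPAC2_BASES[cand] == frozenset(rest):
            # more frequent resolved state is the reference
            resolved = [s for s in ranked if s != cand]
            return {resolved[0]: 0.0, resolved[1]: 1.0, cand: 0.5}
    # no union relation: top two states carry the contrast, third masked
    return {ranked[0]: 0.0, ranked[1]: 1.0, ranked[2]: float("nan")}


def encode_genotypes(matrix: SiteCallMatrix) -> EncodedGenotypes:
    """Map call states to alternate-state dosages per marker.

    Two states -> {0, 1} (reference = most frequent). Three states where one
    is the IUPAC union of the two resolved bases (e.g. A, G, R) -> the union
    code is 0.5. A third state without a union relation is masked as missing.
    """
    n, m = matrix.n_accessions, matrix.n_sites
    dosages = np.full((n, m), np.nan)
    legend = []
    for j in range(m):
        col = matrix.calls[:, j]
        mapping = _encode_column(col)
        legend.append({s: v for s, v in mapping.items() if np.isfinite(v)})
        for state, value in mapping.items():
            if np.isfinite(value):
                dosages[col == state, j] = value
    return EncodedGenotypes(dosages, list(matrix.accession_ids),
                            list(matrix.site_ids), legend)


# ---------------------------------------------------------------------------
# JC69 distances and dendrogram
# ---------------------------------------------------------------------------

def jc69_distance(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p) over shared sites.

    ``p`` is the mismatch proportion over sites non-missing in both
    sequences. Saturated pairs (p >= 0.75) are flagged as ``inf``.
    """
    shared = (calls_i != MISSING) & (calls_j != MISSING)
    if not shared.any():
        raise ValueError("no shared non-missing sites")
    p = float((calls_i[shared] != calls_j[shared]).mean())
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def jc69_matrix(matrix: SiteCallMatrix) -> pd.DataFrame:
    """Pairwise JC69 distance matrix over all accessions."""
    calls = matrix.calls
    n = matrix.n_accessions
    present = calls != MISSING
    dist = np.zeros((n, n))
    for i in range(n):
        shared = present[i] & present[i + 1:]
        n_shared = shared.sum(axis=1)
        if (n_shared == 0).any():
            raise ValueError("accession pair with no shared non-missing sites")
        mism = ((calls[i] != calls[i + 1:]) & shared).sum(axis=1)
        p = mism / n_shared
        with np.errstate(invalid="ignore"):
            d = np.where(p >= 0.75, np.inf, -0.75 * np.log1p(-(4.0 / 3.0) * p))
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return pd.DataFrame(dist, index=matrix.accession_ids,
                        columns=matrix.accession_ids)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    root = tree
    left = rec(root.left, root.dist)
    right = rec(root.right, root.dist)
    return f"({left},{right});"


def build_dendrogram(distances: pd.DataFrame, method: str = "average"):
    """Agglomerate a distance matrix into an ultrametric tree.

    Returns ``(linkage_matrix, newick)``. ``method`` is any scipy linkage
    method (default average / UPGMA) or ``"nj"`` for neighbor joining
    (via scikit-bio; the NJ tree is additive, not ultrametric).
    """
    vals = distances.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("distance matrix contains non-finite entries")
    labels = list(distances.index)
    if method == "nj":
        from skbio import DistanceMatrix
        from skbio.tree import nj

        tree = nj(DistanceMatrix(vals, ids=labels))
        return None, str(tree).strip()
    condensed = squareform(vals, checks=False)
    link = hierarchy.linkage(condensed, method=method)
    return link, _linkage_to_newick(link, labels)


# ---------------------------------------------------------------------------
# Q-matrix (PCA-to-simplex admixture surrogate)
# ---------------------------------------------------------------------------

def _impute_center(dosages: np.ndarray, standardize: bool = False):
    col_mean = np.nanmean(dosages, axis=0)
    filled = np.where(np.isnan(dosages), col_mean, dosages)
    centered = filled - col_mean
    if standardize:
        sd = centered.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {(~keep).sum()} zero-variance markers")
        centered = centered[:, keep] / sd[keep]
    return centered


def _project_simplex_rows(coords: np.ndarray, archetypes: np.ndarray) -> np.ndarray:
    """Least-squares weights on the simplex spanned by archetype rows."""
    k = archetypes.shape[0]
    if k == 2:
        a, b = archetypes[0], archetypes[1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            return np.full((coords.shape[0], 2), 0.5)
        t = np.clip((coords - a) @ ab / denom, 0.0, 1.0)
        return np.column_stack([1.0 - t, t])
    from scipy.optimize import nnls

    # soft sum-to-one via an augmented row, then exact renormalization
    penalty = 1_000.0
    A = np.vstack([archetypes.T, penalty * np.ones(k)])
    out = np.empty((coords.shape[0], k))
    for i, x in enumerate(coords):
        b = np.concatenate([x, [penalty]])
        w, _ = nnls(A, b)
        s = w.sum()
        out[i] = w / s if s > 0 else np.full(k, 1.0 / k)
    return out


def estimate_q(genotypes: EncodedGenotypes, k: int | str = 2,
               seed: int = 0) -> pd.DataFrame:
    """Admixture-proportion (Q) matrix from principal coordinates.

    Column-centered, mean-imputed dosages are decomposed by SVD; accessions
    are mapped onto the (k-1)-simplex spanned by cluster archetypes (the
    most extreme member of each k-means cluster in PC space). With
    ``k="auto"``, k is chosen by the largest eigengap among the first 10
    eigenvalues.
    """
    from sklearn.cluster import KMeans

    n, m = genotypes.n_accessions, genotypes.n_markers
    if m < n / 10:
        raise ValueError(f"too few markers ({m}) for {n} accessions")
    centered = _impute_center(genotypes.dosages)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eig = s ** 2
    if k == "auto":
        top = eig[: min(10, len(eig))]
        gaps = -np.diff(top)
        k = int(np.argmax(gaps)) + 2
    k = int(k)
    if k < 2:
        raise ValueError("k must be >= 2")
    top = eig[: min(10, len(eig))]
    if len(top) > k - 1 and top[k - 2] < 2 * top[k - 1]:
        warnings.warn("weak eigengap: little evidence for k subpopulations")
    scores = u[:, : k - 1] * s[: k - 1]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
    center = scores.mean(axis=0)
    # archetype per cluster: the mean of its outer quartile of points along
    # the direction away from the global centre — a trimmed extreme, robust
    # to single outliers while keeping unadmixed accessions near vertices
    archetypes = np.empty((k, k - 1))
    for c in range(k):
        members = scores[km.labels_ == c]
        direction = members.mean(axis=0) - center
        norm = np.linalg.norm(direction)
        if norm == 0:
            archetypes[c] = members.mean(axis=0)
            continue
        proj = (members - center) @ (direction / norm)
        cut = np.quantile(proj, 0.75)
        archetypes[c] = members[proj >= cut].mean(axis=0)
    q = _project_simplex_rows(scores, archetypes)
    return pd.DataFrame(q, index=genotypes.accession_ids,
                        columns=[f"pop{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship(genotypes: EncodedGenotypes) -> pd.DataFrame:
    """Standardized-dosage kinship K = GG'/m, rescaled to mean diagonal 1."""
    g = _impute_center(genotypes.dosages, standardize=True)
    m = g.shape[1]
    if m == 0:
        raise ValueError("no informative markers for kinship")
    k = g @ g.T / m
    k /= np.mean(np.diag(k))
    k = (k + k.T) / 2
    return pd.DataFrame(k, index=genotypes.accession_ids,
                        columns=genotypes.accession_ids)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    """Per-chromosome pairwise r-squared and its means.

    ``pairs`` columns: chromosome, site_i, site_j, r2. The genome mean
    averages over all retained within-chromosome pairs.
    """

    pairs: pd.DataFrame
    chromosome_means: pd.Series
    genome_mean: float
    sites_used: list[str] = field(default_factory=list)


def ld_scan(genotypes: EncodedGenotypes, annotations: pd.DataFrame,
            seed: int = 1, maf_min: float = 0.01) -> LDResult:
    """Pairwise dosage r-squared per chromosome.

    Markers enter only when genome-assigned and with MAF above ``maf_min``;
    one site is drawn at random (seeded) per CDS model so a gene's many
    linked SNPs contribute once. r-squared is the squared Pearson correlation
    of dosages over pairwise-complete accessions; in inbred/DH material this
    equals the haplotype r-squared.
    """
    rng = np.random.default_rng(seed)
    ann = annotations[
        annotations["genome_assigned"] & (annotations["maf"] > maf_min)
    ]
    chosen = []
    for model, grp in sorted(ann.groupby("model"), key=lambda t: t[0]):
        site_ids = sorted(grp["site_id"])
        chosen.append(site_ids[rng.integers(len(site_ids))])
    ann = ann.set_index("site_id").loc[chosen]

    pair_frames = []
    chrom_means = {}
    for chrom, grp in ann.groupby("chromosome"):
        sites = sorted(grp.index, key=lambda s: int(grp.loc[s, "order_index"]))
        if len(sites) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 sites, skipped")
            continue
        sub = genotypes.select_sites(sites).frame()
        corr = sub.corr(min_periods=2)
        r2 = corr.to_numpy() ** 2
        iu = np.triu_indices(len(sites), k=1)
        pair_frames.append(pd.DataFrame({
            "chromosome": chrom,
            "site_i": [sites[i] for i in iu[0]],
            "site_j": [sites[j] for j in iu[1]],
            "r2": r2[iu],
        }))
        chrom_means[chrom] = float(np.nanmean(r2[iu]))
    if pair_frames:
        pairs = pd.concat(pair_frames, ignore_index=True)
        genome_mean = float(np.nanmean(pairs["r2"]))
    else:
        pairs = pd.DataFrame(columns=["chromosome", "site_i", "site_j", "r2"])
        genome_mean = float("nan")
    return LDResult(pairs, pd.Series(chrom_means, dtype=float), genome_mean,
                    sites_used=list(ann.index))
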