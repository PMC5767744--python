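import numpy as np
import pandas as pd
import pytest

from assoctx.io import SiteCallMatrix
from assoctx.structure import (
    EncodedGenotypes,
    build_dendrogram,
    encode_genotypes,
    estimate_q,
    jc69_distance,
    jc69_matrix,
    kinship,
    ld_scan,
)


class TestEncoding:
    def test_two_state_marker(self):
        m = SiteCallMatrix(np.array([["A"], ["R"], ["A"]]),
                           ["a", "b", "c"], ["s1"])
        enc = encode_genotypes(m)
        assert enc.dosages[0, 0] == 0.0 and enc.dosages[1, 0] == 1.0

    def test_union_code_is_midpoint(self):
        m = SiteCallMatrix(np.array([["A"], ["G"], ["R"], ["A"]]),
                           list("abcd"), ["s1"])
        enc = encode_genotypes(m)
        assert enc.dosages[2, 0] == 0.5
        assert enc.legend[0] == {"A": 0.0, "G": 1.0, "R": 0.5}

    def test_missing_masked(self):
        m = SiteCallMatrix(np.array([["A"], ["N"], ["G"]]),
                           list("abc"), ["s1"])
        enc = encode_genotypes(m)
        assert np.isnan(enc.dosages[1, 0])


class TestJC69:
    def test_identity_is_zero(self):
        x = np.array(["A", "G", "T", "C"])
        assert jc69_distance(x, x) == 0.0

    def test_closed_form_at_p_005(self):
        x = np.array(["A"] * 100)
        y = x.copy()
        y[:5] = "G"
        assert jc69_distance(x, y) == pytest.approx(0.05176, abs=5e-5)

    def test_saturation_flagged(self):
        x = np.array(["A"] * 10)
        y = np.array(["G"] * 8 + ["A"] * 2)
        assert np.isinf(jc69_distance(x, y))

    def test_no_shared_sites_errors(self):
        with pytest.raises(ValueError, match="shared"):
            jc69_distance(np.array(["A", "N"]), np.array(["N", "G"]))

    def test_matrix_agrees_with_pairwise(self, called_small):
        matrix, _, _ = called_small
        sub = matrix.select_accessions(matrix.accession_ids[:6])
        d = jc69_matrix(sub)
        for i, a in enumerate(sub.accession_ids):
            for j, b in enumerate(sub.accession_ids):
                if i < j:
                    assert d.iloc[i, j] == pytest.approx(
                        jc69_distance(sub.accession(a), sub.accession(b)))
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestDendrogram:
    def _dist(self, order):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]],
            index=["x", "y", "z"], columns=["x", "y", "z"])
        return d.loc[order, order]

    @staticmethod
    def _innermost_pair(newick):
        # deepest parenthesized clade = first closing paren back to its opener
        close = newick.index(")")
        open_ = newick.rindex("(", 0, close)
        return {t.split(":")[0] for t in newick[open_ + 1:close].split(",")}

    def test_topology_forced_by_distances(self):
        _, newick = build_dendrogram(self._dist(["x", "y", "z"]))
        assert self._innermost_pair(newick) == {"x", "y"}

    def test_permutation_invariant_topology(self):
        _, a = build_dendrogram(self._dist(["x", "y", "z"]))
        _, b = build_dendrogram(self._dist(["z", "x", "y"]))
        assert self._innermost_pair(a) == self._innermost_pair(b) == {"x", "y"}

    def test_identical_accessions_zero_height(self):
        d = pd.DataFrame(np.zeros((2, 2)), index=["x", "y"],
                         columns=["x", "y"])
        link, _ = build_dendrogram(d)
        assert link[0, 2] == 0.0

    def test_nonfinite_distance_rejected(self):
        d = self._dist(["x", "y", "z"])
        d.iloc[0, 1] = d.iloc[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            build_dendrogram(d)


def _two_pop_genotypes(n=100, m=400, fst=0.3, seed=0, admixed=None):
    rng = np.random.default_rng(seed)
    panc = rng.uniform(0.05, 0.95, m)
    fr = rng.beta(panc * (1 - fst) / fst, (1 - panc) * (1 - fst) / fst,
                  size=(2, m))
    labels = np.arange(n) % 2
    admix = np.zeros((n, 2))
    admix[np.arange(n), labels] = 1.0
    if admixed is not None:
        admix[admixed] = [0.5, 0.5]
    freq = admix @ fr
    d = (rng.random((n, m)) < freq).astype(float)
    ids = [f"a{i}" for i in range(n)]
    sites = [f"m{j:03d}:1" for j in range(m)]
    enc = EncodedGenotypes(d, ids, sites, [{} for _ in range(m)])
    return enc, labels, admix


class TestQMatrix:
    def test_unadmixed_recovery(self):
        enc, labels, _ = _two_pop_genotypes()
        q = estimate_q(enc, 2, seed=0)
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-9)
        hard = q.to_numpy().argmax(axis=1)
        acc = max((hard == labels).mean(), (hard != labels).mean())
        assert acc >= 0.95
        # unadmixed accessions sit near the simplex vertices
        assert np.median(q.to_numpy().max(axis=1)) > 0.9

    def test_admixed_accession_near_midpoint(self):
        enc, _, _ = _two_pop_genotypes(n=101, admixed=100, seed=1)
        q = estimate_q(enc, 2, seed=1)
        assert abs(q.iloc[100, 0] - 0.5) <= 0.15

    def test_k_below_two_rejected_and_no_structure_warns(self):
        enc, _, _ = _two_pop_genotypes(fst=0.3)
        with pytest.raises(ValueError):
            estimate_q(enc, 1)
        rng = np.random.default_rng(5)
        flat = EncodedGenotypes(
            rng.binomial(1, 0.5, size=(60, 300)).astype(float),
            [f"a{i}" for i in range(60)],
            [f"m{j}:1" for j in range(300)], [{}] * 300)
        with pytest.warns(UserWarning, match="eigengap"):
            estimate_q(flat, 2, seed=0)


class TestKinship:
    def test_duplicate_accessions_maximal_entry(self):
        enc, _, _ = _two_pop_genotypes(n=40, m=300, seed=2)
        d = enc.dosages.copy()
        d[1] = d[0]
        dup = EncodedGenotypes(d, enc.accession_ids, enc.site_ids, enc.legend)
        k = kinship(dup).to_numpy()
        off = k - np.diag(np.diag(k))
        assert np.unravel_index(np.argmax(off), off.shape) in [(0, 1), (1, 0)]

    def test_unrelated_offdiagonals_vanish(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(1, 0.5, size=(30, 5000)).astype(float)
        enc = EncodedGenotypes(d, [f"a{i}" for i in range(30)],
                               [f"m{j}:1" for j in range(5000)], [{}] * 5000)
        k = kinship(enc).to_numpy()
        off = k[~np.eye(30, dtype=bool)]
        assert np.abs(off).max() < 0.12 and np.abs(off).mean() < 0.05

    def test_symmetric_psd_unit_mean_diagonal(self, structured_small):
        _, _, k = structured_small
        arr = k.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.linalg.eigvalsh(arr).min() > -1e-8
        assert np.diag(arr).mean() == pytest.approx(1.0)


class TestLD:
    def _setup(self, n=300, m=60, seed=4):
        rng = np.random.default_rng(seed)
        d = rng.binomial(1, 0.5, size=(n, m)).astype(float)
        ids = [f"a{i}" for i in range(n)]
        sites = [f"g{j:03d}:1" for j in range(m)]
        enc = EncodedGenotypes(d, ids, sites, [{}] * m)
        ann = pd.DataFrame({
            "site_id": sites,
            "model": [f"g{j:03d}" for j in range(m)],
            "snp_class": "simple",
            "genome_assigned": True,
            "maf": 0.4,
            "chromosome": "A1",
            "order_index": np.arange(1, m + 1),
        })
        return enc, ann

    def test_duplicated_marker_r2_one(self):
        enc, ann = self._setup(m=3)
        enc.dosages[:, 1] = enc.dosages[:, 0]
        res = ld_scan(enc, ann, seed=1)
        pair = res.pairs.set_index(["site_i", "site_j"])
        assert pair.loc[("g000:1", "g001:1"), "r2"] == pytest.approx(1.0)

    def test_null_mean_matches_expectation(self):
        enc, ann = self._setup()
        res = ld_scan(enc, ann, seed=1)
        assert res.genome_mean == pytest.approx(1 / 299, rel=0.35)

    def test_seeded_selection_deterministic(self, structured_small,
                                            called_small):
        geno, _, _ = structured_small
        _, ann, _ = called_small
        a = ld_scan(geno, ann, seed=11)
        b = ld_scan(geno, ann, seed=11)
        assert a.sites_used == b.sites_used
        assert a.genome_mean == b.genome_mean
        assert (a.pairs["r2"].to_numpy() >= 0).all()
        assert (a.pairs["r2"].to_numpy() <= 1 + 1e-12).all()
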