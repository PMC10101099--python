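"""Alpha diversity, dissimilarities, LCBD and phylogenetic structure.

Alpha diversity uses Renyi-Hill numbers: order q=0 is OTU richness, q=1
the exponential of Shannon entropy, q=2 the inverse Simpson concentration.
Beta diversity supports Bray-Curtis (counts), Hellinger (Euclidean
distance between square-rooted proportion vectors) and both UniFrac
variants (phylogenetic). LCBD decomposes total beta diversity into
per-sample contributions via Gower centering. NRI/NTI measure phylogenetic
clustering of each sample against a richness-preserving null drawn from
the most abundant OTUs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_model import (DissimilarityMatrix, OtuTable, PhyloTree,
                         ValidationError)
from .community import relative_abundance

METRICS = ("bray_curtis", "hellinger", "unifrac_unweighted",
           "unifrac_weighted")


def hill_number(p: np.ndarray, q: float) -> float:
    """Effective number of species of order q for a proportion vector.

    q=0 gives richness, q=1 exp(Shannon entropy) (the q->1 limit), q=2 the
    inverse Simpson index; the function is defined for any real q >= 0 as
    (sum_i p_i^q)^(1/(1-q)) over positive entries.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.all(p == 0):
        raise ValidationError("empty or all-zero proportion vector")
    if np.any(p < 0):
        raise ValidationError("proportions must be >= 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions must sum to 1 (got {p.sum()!r})")
    if q < 0:
        raise ValueError("q must be >= 0")
    pos = p[p > 0]
    if q == 1:
        return float(np.exp(-np.sum(pos * np.log(pos))))
    return float(np.sum(pos ** q) ** (1.0 / (1.0 - q)))


def alpha_diversity(table: OtuTable, orders=(0, 1, 2)) -> dict[str, np.ndarray]:
    """Hill numbers of the given orders for every sample."""
    rel = relative_abundance(table)
    out = {f"q{q:g}": np.array([hill_number(row, q) for row in rel])
           for q in orders}
    out["sample_id"] = np.array(table.sample_ids)
    return out


def _bray_curtis(counts: np.ndarray) -> np.ndarray:
    x = counts.astype(float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        tot = (x[i] + x[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            val = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        d[i, i + 1:] = val
        d[i + 1:, i] = val
    return d


def _branch_table(tree: PhyloTree, otu_ids: list[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch-by-OTU membership of the tree.

    Row b of the membership matrix marks the OTUs descending from branch b.
    Works on any rooted tree, bifurcating or not.
    """
    col = {o: j for j, o in enumerate(otu_ids)}
    lengths, rows = [], []
    for node in tree.tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] or [node.name]
        row = np.zeros(len(otu_ids), dtype=bool)
        for t in tips:
            if t in col:
                row[col[t]] = True
        lengths.append(float(node.length))
        rows.append(row)
    return np.asarray(lengths), np.asarray(rows)


def _unifrac(table: OtuTable, tree: PhyloTree, weighted: bool) -> np.ndarray:
    """Pairwise UniFrac by summation over branches.

    Unweighted: branch length found in exactly one of the two samples over
    branch length found in either. Weighted (normalized): with p(b) the
    fraction of a sample's reads descending from branch b,
    sum_b l_b |p_A(b) - p_B(b)| / sum_b l_b (p_A(b) + p_B(b)).
    """
    lengths, member = _branch_table(tree, table.otu_ids)
    n = table.n_samples
    d = np.zeros((n, n))
    if weighted:
        rel = relative_abundance(table)
        p = rel @ member.T  # samples x branches
        wp = p * lengths
        for i in range(n):
            num = np.abs(wp[i] - wp[i + 1:]).sum(axis=1)
            den = (wp[i] + wp[i + 1:]).sum(axis=1)
            val = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            d[i, i + 1:] = val
            d[i + 1:, i] = val
    else:
        present = (table.counts > 0) @ member.T > 0  # samples x branches
        for i in range(n):
            either = present[i] | present[i + 1:]
            both = present[i] & present[i + 1:]
            union = (either * lengths).sum(axis=1)
            shared = (both * lengths).sum(axis=1)
            val = np.where(union > 0, (union - shared) /
                           np.where(union > 0, union, 1.0), 0.0)
            d[i, i + 1:] = val
            d[i + 1:, i] = val
    return d


def dissimilarity(table: OtuTable, metric: str,
                  tree: PhyloTree | None = None) -> DissimilarityMatrix:
    """Sample-by-sample dissimilarity matrix under the named metric.

    UniFrac variants require a tree covering every OTU in the table;
    weighted UniFrac is the normalized form, bounded in [0, 1].
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric.startswith("unifrac"):
        if tree is None:
            raise ValidationError(f"{metric} requires a phylogenetic tree")
        missing = set(table.otu_ids) - set(tree.leaf_names)
        if missing:
            raise ValidationError(
                f"tree is missing OTUs: {sorted(missing)[:10]}")
        values = _unifrac(table, tree, weighted=metric == "unifrac_weighted")
    elif metric == "bray_curtis":
        values = _bray_curtis(table.counts)
    else:  # hellinger
        root_p = np.sqrt(relative_abundance(table))
        values = squareform(pdist(root_p, metric="euclidean"))
    values = np.asarray(values, dtype=float)
    values = (values + values.T) / 2.0  # kill last-bit asymmetry
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(values, list(table.sample_ids), metric)


def lcbd(d: DissimilarityMatrix) -> np.ndarray:
    """Local contributions to beta diversity; values sum to 1.

    Gower-center the matrix of squared dissimilarities,
    G = -1/2 C D^2 C with C = I - 11'/n; LCBD_i = G_ii / trace(G).
    """
    D2 = d.values ** 2
    n = D2.shape[0]
    if n < 2:
        raise ValidationError("LCBD needs at least 2 samples")
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * C @ D2 @ C
    total = np.trace(G)
    if total <= 1e-12:
        raise ValidationError("no beta diversity: all samples identical")
    return np.diag(G) / total


@dataclass
class SesResult:
    """Standardized effect size of a phylogenetic distance statistic.

    ``index_value`` is the negated SES: NRI for MPD, NTI for MNTD. Values
    above 2 are read as strong phylogenetic clustering (environmental
    filtering); values below -2 as overdispersion.
    """

    sample_id: str
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    index_value: float
    n_null: int
    defined: bool = True

    @property
    def clustered(self) -> bool:
        return self.defined and self.index_value > 2.0


def _mpd(dist: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Mean pairwise distance for each row of presence indices idx."""
    sub = dist[idx[..., :, None], idx[..., None, :]]
    k = idx.shape[-1]
    return sub.sum(axis=(-2, -1)) / (k * (k - 1))


def _mntd(dist: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Mean nearest-taxon distance for each row of presence indices idx."""
    sub = dist[idx[..., :, None], idx[..., None, :]].copy()
    k = idx.shape[-1]
    eye = np.eye(k, dtype=bool)
    sub[..., eye] = np.inf
    return sub.min(axis=-1).mean(axis=-1)


def top_abundant_otus(table: OtuTable, top_k: int) -> list[str]:
    """The top_k most abundant OTUs by total count, ties broken by id."""
    totals = table.counts.sum(axis=0)
    order = sorted(range(table.n_otus),
                   key=lambda j: (-totals[j], table.otu_ids[j]))
    return [table.otu_ids[j] for j in order[:top_k]]


def sample_seed(master_seed: int, sample_id: str) -> int:
    """Per-sample RNG seed derived by hashing; order-independent."""
    h = zlib.crc32(f"{master_seed}:{sample_id}".encode())
    return int(h) % (2**31 - 1)


def ses_phylo(table: OtuTable, tree: PhyloTree, metric: str = "MPD",
              n_null: int = 999, top_k: int = 1000,
              seed: int = 0) -> list[SesResult]:
    """NRI/NTI: standardized effect size of MPD or MNTD per sample.

    Presence/absence only, restricted to the pool of the ``top_k`` most
    abundant OTUs. The null model preserves each sample's richness and
    draws taxa uniformly from the pool ("richness" null). When the null
    distribution has zero spread the index is flagged undefined rather
    than fabricated.
    """
    if metric not in ("MPD", "MNTD"):
        raise ValueError("metric must be 'MPD' or 'MNTD'")
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    pool = top_abundant_otus(table, top_k)
    sub = table.select_otus(pool)
    dist = tree.patristic_distances(pool)
    stat = _mpd if metric == "MPD" else _mntd
    P = len(pool)
    results = []
    for i, sid in enumerate(table.sample_ids):
        present = np.nonzero(sub.counts[i] > 0)[0]
        k = present.size
        if k < 2:
            raise ValidationError(
                f"sample {sid!r} has fewer than 2 OTUs in the top-{top_k} pool")
        observed = float(stat(dist, present))
        rng = np.random.default_rng(sample_seed(seed, sid))
        # richness null: k taxa drawn uniformly without replacement
        draws = np.argpartition(rng.random((n_null, P)), k - 1,
                                axis=1)[:, :k]
        null_vals = stat(dist, draws)
        mu, sd = float(null_vals.mean()), float(null_vals.std(ddof=1))
        if sd > 1e-12 * max(1.0, abs(mu)):  # spread beyond rounding noise
            ses = (observed - mu) / sd
            results.append(SesResult(sid, metric, observed, mu, sd,
                                     ses, -ses, n_null))
        else:
            results.append(SesResult(sid, metric, observed, mu, sd,
                                     float("nan"), float("nan"), n_null,
                                     defined=False))
    return results
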