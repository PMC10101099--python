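"""BVSTEP: minimal OTU subset whose dissimilarity structure matches the
full community's.

The fixed reference is the dissimilarity matrix of the full (top-k
restricted) table; the search alternates forward steps (add the OTU that
maximizes the Spearman rank correlation rho between the subset and
reference dissimilarity vectors) with backward sweeps (drop any OTU whose
removal does not reduce rho by more than a small tolerance), stopping when
rho reaches the target or no improving move exists.

For Bray-Curtis the subset dissimilarities decompose into per-OTU pairwise
contributions (numerator sum of |x_i - y_i|, denominator sum of x_i + y_i),
so candidate moves are evaluated incrementally instead of rebuilding the
matrix; other metrics fall back to full recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from scipy.spatial.distance import pdist

from .community import relative_abundance
from .data_model import OtuTable, PhyloTree
from .diversity import dissimilarity, top_abundant_otus

DROP_TOLERANCE = 1e-6
_CACHE_BUDGET = 5e7  # floats; per-OTU pair contributions kept below this


@dataclass
class BvstepResult:
    selected_otu_ids: list[str]
    rho: float
    converged: bool
    n_evaluations: int
    trace: list[tuple[str, str, float]] = field(default_factory=list)


class _SubsetScorer:
    """Spearman rho between the fixed dissimilarity vector and a subset's."""

    def __init__(self, table: OtuTable, metric: str,
                 tree: PhyloTree | None) -> None:
        self.table = table
        self.metric = metric
        self.tree = tree
        fixed = dissimilarity(table, metric, tree).condensed()
        self._fixed_ranks = rankdata(fixed)
        self._fixed_ranks -= self._fixed_ranks.mean()
        self._fixed_norm = float(np.sqrt((self._fixed_ranks ** 2).sum()))
        n = table.n_samples
        self._iu = np.triu_indices(n, k=1)
        self._bc = metric == "bray_curtis"
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._may_cache = (table.n_otus * self._iu[0].size) <= _CACHE_BUDGET
        self.n_evaluations = 0
        # Hellinger: the square-root-proportion transform is applied once
        # to the full table; a subset is a column selection of the
        # transformed matrix (renormalizing within each candidate subset
        # would make single-OTU subsets degenerate)
        self._hell = (np.sqrt(relative_abundance(table))
                      if metric == "hellinger" else None)

    def _contrib(self, otu: str) -> tuple[np.ndarray, np.ndarray]:
        got = self._cache.get(otu)
        if got is not None:
            return got
        x = self.table.counts[:, self.table.otu_ids.index(otu)].astype(float)
        pair = (np.abs(x[self._iu[0]] - x[self._iu[1]]),
                x[self._iu[0]] + x[self._iu[1]])
        if self._may_cache:
            self._cache[otu] = pair
        return pair

    def subset_state(self, subset: list[str]):
        """Accumulated (numerator, denominator) pair sums for a subset."""
        num = np.zeros(self._iu[0].size)
        den = np.zeros(self._iu[0].size)
        for otu in subset:
            dn, dd = self._contrib(otu)
            num = num + dn
            den = den + dd
        return num, den

    def _rho_of_vector(self, vec: np.ndarray) -> float:
        ranks = rankdata(vec)
        ranks -= ranks.mean()
        denom = self._fixed_norm * np.sqrt((ranks ** 2).sum())
        if denom == 0:
            return float("-inf")
        rho = float((self._fixed_ranks @ ranks) / denom)
        return rho if np.isfinite(rho) else float("-inf")

    def score_state(self, num: np.ndarray, den: np.ndarray) -> float:
        self.n_evaluations += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            vec = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return self._rho_of_vector(vec)

    def score(self, subset: list[str]) -> float:
        if self._bc:
            return self.score_state(*self.subset_state(subset))
        self.n_evaluations += 1
        if self._hell is not None:
            cols = [self.table.otu_ids.index(o) for o in subset]
            vec = pdist(self._hell[:, cols], metric="euclidean")
        else:
            vec = dissimilarity(self.table.select_otus(subset), self.metric,
                                self.tree).condensed()
        return self._rho_of_vector(vec)


def bvstep_select(table: OtuTable, metric: str = "bray_curtis",
                  rho_target: float = 0.95, top_k: int = 1000,
                  tree: PhyloTree | None = None, seed: int = 0,
                  max_steps: int = 1000) -> BvstepResult:
    """Greedy forward/backward search for a minimal structure-bearing subset.

    Ties between candidate OTUs are broken lexicographically; the search is
    deterministic from the empty set.
    """
    if table.n_samples < 3:
        raise ValueError("BVSTEP needs at least 3 samples")
    if not 0 < rho_target <= 1:
        raise ValueError("rho_target must be in (0, 1]")
    pool = top_abundant_otus(table, top_k)
    work = table.select_otus(pool)
    scorer = _SubsetScorer(work, metric, tree)
    fast = metric == "bray_curtis"

    selected: list[str] = []
    rho_cur = float("-inf")
    trace: list[tuple[str, str, float]] = []
    for _ in range(max_steps):
        if rho_cur >= rho_target:
            break
        # forward: best single addition (lexicographic tie-break)
        best_rho, best_otu = rho_cur, None
        if fast:
            num, den = scorer.subset_state(selected)
        for otu in sorted(set(pool) - set(selected)):
            if fast:
                dn, dd = scorer._contrib(otu)
                cand_rho = scorer.score_state(num + dn, den + dd)
            else:
                cand_rho = scorer.score(selected + [otu])
            if cand_rho > best_rho + 1e-12:
                best_rho, best_otu = cand_rho, otu
        if best_otu is None:
            break
        selected = sorted(selected + [best_otu])
        rho_cur = best_rho
        trace.append(("add", best_otu, rho_cur))
        # backward: drop anything that costs less than the tolerance
        # (the OTU just added is exempt, so add/drop cycles cannot occur)
        improved = True
        while improved and len(selected) > 1:
            improved = False
            for otu in sorted(o for o in selected if o != best_otu):
                remaining = [o for o in selected if o != otu]
                cand_rho = scorer.score(remaining)
                if cand_rho >= rho_cur - DROP_TOLERANCE:
                    selected = remaining
                    rho_cur = cand_rho
                    trace.append(("drop", otu, rho_cur))
                    improved = True
                    break
    converged = rho_cur >= rho_target
    return BvstepResult(selected_otu_ids=selected, rho=rho_cur,
                        converged=converged,
                        n_evaluations=scorer.n_evaluations, trace=trace)
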