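"""Significance Analysis of Microarrays (SAM) for two-group comparisons.

SAM scores each gene with a moderated difference statistic

    d_i = (mean_A - mean_B) / (s_i + s0)

where ``s_i`` is the pooled two-sample standard error and the "fudge
constant" ``s0`` damps the inflation of d at low signal variance.  ``s0``
is chosen by the SAM convention: the percentile of the per-gene standard
errors that minimizes the coefficient of variation of the median absolute
deviation of d across bins of s (a fixed percentile can be forced instead).

Significance comes from permutations of the group labels: for each gene the
q-value is the median, over permutations, of the number of null statistics
at least as extreme as |d_i|, divided by the observed count at that
threshold, then made monotone in the |d| ranking.  A gene is called up
(down) only when it passes both the q-value bound and a raw-scale fold-change
cut-off computed from the de-logged group means.

Usage::

    model = SamModel(gene_matrix, groups, "blood", "solid")
    res = model.fit(n_perm=100, fold=2.0, fdr=0.05, seed=1)
    res.summary()

``venn_signatures`` decomposes two up- (or down-) regulated gene lists into
common and group-specific signature sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import SampleGroups

__all__ = ["SamModel", "SamResults", "SignatureVenn", "venn_signatures"]

logger = logging.getLogger(__name__)


def _positive(den: np.ndarray) -> np.ndarray:
    """Clamp a denominator away from zero (degenerate zero-variance genes)."""
    return np.where(den > 0, den, np.finfo(float).tiny)


class SamModel:
    """Two-group SAM model over a gene-level expression matrix.

    Parameters
    ----------
    endog : pandas.DataFrame
        Genes x samples log2 expression.
    groups : SampleGroups or dict
        Sample -> group-label assignment covering the matrix columns.
    group_a, group_b : str
        The two labels to contrast; d > 0 means higher in ``group_a``.
    """

    def __init__(self, endog: pd.DataFrame, groups, group_a: str, group_b: str):
        if isinstance(groups, SampleGroups):
            assignment = groups.assignment
        else:
            assignment = dict(groups)
        self.endog = endog
        samples_a = [s for s in endog.columns if assignment.get(s) == group_a]
        samples_b = [s for s in endog.columns if assignment.get(s) == group_b]
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError(
                f"need >=2 samples per group: {group_a}={len(samples_a)}, "
                f"{group_b}={len(samples_b)}"
            )
        self.group_a, self.group_b = group_a, group_b
        self.samples_a, self.samples_b = samples_a, samples_b

    # -- statistic ---------------------------------------------------------

    @staticmethod
    def _d_stat(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                s0: float) -> np.ndarray:
        mean_a = values[:, idx_a].mean(axis=1)
        mean_b = values[:, idx_b].mean(axis=1)
        s = SamModel._pooled_se(values, idx_a, idx_b)
        return (mean_a - mean_b) / _positive(s + s0)

    @staticmethod
    def _pooled_se(values: np.ndarray, idx_a: np.ndarray,
                   idx_b: np.ndarray) -> np.ndarray:
        na, nb = len(idx_a), len(idx_b)
        ssa = values[:, idx_a].var(axis=1, ddof=1) * (na - 1)
        ssb = values[:, idx_b].var(axis=1, ddof=1) * (nb - 1)
        pooled = (ssa + ssb) / (na + nb - 2)
        return np.sqrt(pooled * (1.0 / na + 1.0 / nb))

    @staticmethod
    def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
        """SAM fudge-factor rule: the percentile of s minimizing the CV of
        the MADs of d over quantile bins of s.  ``r`` is the raw mean
        difference (d numerator)."""
        candidates = np.percentile(s, np.arange(0, 101, 5))
        n_bins = max(3, min(100, len(s) // 20))
        # quantile bin edges on s, shared by all candidates
        edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
        bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
        best, best_cv = float(candidates[0]), math.inf
        for s0 in candidates:
            d = r / _positive(s + s0)
            mads = np.array(
                [np.median(np.abs(d[bins == b] - np.median(d[bins == b])))
                 for b in range(n_bins) if (bins == b).any()]
            )
            mu = mads.mean()
            cv = mads.std(ddof=0) / mu if mu > 0 else math.inf
            if cv < best_cv:
                best_cv, best = cv, float(s0)
        return best

    # -- permutations ------------------------------------------------------

    def _permutation_indices(self, n_perm: int, seed) -> list[np.ndarray]:
        """Index sets taking the role of group A under the permutation null."""
        n = len(self.samples_a) + len(self.samples_b)
        na = len(self.samples_a)
        total = math.comb(n, na)
        if total <= n_perm:
            logger.warning(
                "requested %d permutations but only %d distinct label "
                "assignments exist; enumerating exhaustively", n_perm, total,
            )
            return [np.array(c) for c in combinations(range(n), na)]
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, ...]] = set()
        out: list[np.ndarray] = []
        while len(out) < n_perm:
            pick = tuple(sorted(rng.choice(n, size=na, replace=False).tolist()))
            if pick not in seen:
                seen.add(pick)
                out.append(np.array(pick))
        return out

    # -- fit ---------------------------------------------------------------

    def fit(self, n_perm: int = 100, fold: float = 2.0, fdr: float = 0.05,
            seed: int | None = 0, s0_percentile: float | None = None
            ) -> "SamResults":
        """Run SAM and return a :class:`SamResults`.

        Parameters
        ----------
        n_perm : int
            Label permutations for the null (exhaustive if fewer exist).
        fold : float
            Raw-scale fold-change cut-off (applied symmetrically: up needs
            fold-change >= fold, down needs <= 1/fold).
        fdr : float
            q-value bound for a call.
        s0_percentile : float, optional
            Force s0 to this percentile of the per-gene standard errors
            instead of the automatic CV-minimizing rule.
        """
        cols = self.samples_a + self.samples_b
        values = self.endog[cols].to_numpy(dtype=float)
        idx_a = np.arange(len(self.samples_a))
        idx_b = np.arange(len(self.samples_a), len(cols))

        r = values[:, idx_a].mean(axis=1) - values[:, idx_b].mean(axis=1)
        s = self._pooled_se(values, idx_a, idx_b)
        if s0_percentile is not None:
            s0 = float(np.percentile(s, s0_percentile))
        else:
            s0 = self._choose_s0(r, s)

        d = r / _positive(s + s0)
        abs_d = np.abs(d)

        perms = self._permutation_indices(n_perm, seed)
        all_idx = np.arange(len(cols))
        # null |d| pooled per permutation; count exceedances at each observed |d|
        sorted_abs = np.sort(abs_d)
        fp_counts = np.empty((len(perms), len(d)))
        for k, pa in enumerate(perms):
            pb = np.setdiff1d(all_idx, pa, assume_unique=True)
            d_null = np.abs(self._d_stat(values, pa, pb, s0))
            d_null.sort()
            # exceedance count of each observed threshold in this null set
            fp_counts[k] = len(d_null) - np.searchsorted(d_null, abs_d, side="left")
        median_fp = np.median(fp_counts, axis=0)
        observed = len(abs_d) - np.searchsorted(sorted_abs, abs_d, side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(observed > 0, median_fp / observed, 0.0)
        q = np.clip(q, 0.0, 1.0)
        # enforce monotonicity: larger |d| never has larger q
        order = np.argsort(-abs_d, kind="stable")
        q_sorted = np.maximum.accumulate(q[order])
        q = np.empty_like(q_sorted)
        q[order] = q_sorted

        fold_change = 2.0 ** r  # de-logged ratio of group means
        call = np.full(len(d), "ns", dtype=object)
        call[(fold_change >= fold) & (q <= fdr)] = "up"
        call[(fold_change <= 1.0 / fold) & (q <= fdr)] = "down"

        frame = pd.DataFrame(
            {"d": d, "fold": fold_change, "q": q, "call": call},
            index=self.endog.index,
        )
        frame.index.name = "gene_id"
        return SamResults(self, frame, s0=s0, n_perm=len(perms),
                          fold_threshold=fold, fdr=fdr)


@dataclass
class SamResults:
    """SAM fit results: per-gene d statistic, fold change, q-value and call."""

    model: SamModel
    frame: pd.DataFrame
    s0: float
    n_perm: int
    fold_threshold: float
    fdr: float

    @property
    def up_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["call"] == "up"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["call"] == "down"])

    def summary(self) -> str:
        m = self.model
        n_up, n_down = len(self.up_genes), len(self.down_genes)
        lines = [
            "SAM two-group comparison",
            f"  contrast:      {m.group_a} (n={len(m.samples_a)}) vs "
            f"{m.group_b} (n={len(m.samples_b)})",
            f"  genes:         {len(self.frame)}",
            f"  permutations:  {self.n_perm}",
            f"  s0:            {self.s0:.4g}",
            f"  criteria:      fold >= {self.fold_threshold:g}, "
            f"q <= {self.fdr:g}",
            f"  calls:         {n_up} up, {n_down} down, "
            f"{len(self.frame) - n_up - n_down} ns",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SignatureVenn:
    """Decomposition of two differential gene lists into signature sets."""

    common: frozenset
    a_specific: frozenset
    b_specific: frozenset

    @property
    def union_size(self) -> int:
        return len(self.common) + len(self.a_specific) + len(self.b_specific)

    def cardinalities(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "a_specific": len(self.a_specific),
            "b_specific": len(self.b_specific),
            "union": self.union_size,
        }


def venn_signatures(up_a: set, up_b: set) -> SignatureVenn:
    """Exact set algebra on two differential gene lists.

    The intersection is the "common" signature (for the study design: genes
    regulated in both whole blood and CD34+ HSPC versus solid tissues); the
    differences are the group-specific signatures.
    """
    up_a, up_b = set(up_a), set(up_b)
    common = up_a & up_b
    return SignatureVenn(
        common=frozenset(common),
        a_specific=frozenset(up_a - common),
        b_specific=frozenset(up_b - common),
    )
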