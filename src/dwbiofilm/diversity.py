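"""OTU clustering and alpha diversity.

Reads are clustered into operational taxonomic units (OTUs) by complete
linkage on pairwise sequence distances — an OTU at distance threshold t is a
group whose *maximum* intra-group distance is <= t (0.03 is the usual
species-level proxy, 0.06 genus-level).  From the per-sample OTU counts the
module computes the Chao1 richness estimator, Shannon entropy, Pielou's
evenness and exact (hypergeometric) rarefaction curves.

Distances come from pairwise global alignment with free terminal gaps
(match +1 / mismatch -1 / gap -2): distance = differing columns / aligned
columns, terminal-gap columns excluded.  A pre-computed multiple alignment
can be supplied instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .records import SeqRead


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix over read ids, values in [0, 1]."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if np.diag(self.d).any():
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any() or (self.d > 1).any():
            raise ValueError("distances must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.d[ia, ib])


def _make_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_gap_score = 0  # terminal gaps free
    return aligner


def _aligned_distance(row_a: str, row_b: str) -> float:
    """Distance over non-terminal columns of two gapped rows."""
    n = len(row_a)
    start = 0
    while start < n and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    stop = n
    while stop > start and (row_a[stop - 1] == "-" or row_b[stop - 1] == "-"):
        stop -= 1
    # interior columns where exactly one row is gapped still count
    cols = diffs = 0
    for a, b in zip(row_a[start:stop], row_b[start:stop]):
        if a == "-" and b == "-":
            continue
        cols += 1
        if a != b:
            diffs += 1
    return diffs / cols if cols else 0.0


def pairwise_distance(reads: Sequence[SeqRead],
                      mode: str = "pairwise") -> DistanceMatrix:
    """All-vs-all sequence distances.

    mode="pairwise": global alignment per pair (see module docstring).
    mode="aligned": reads are rows of one multiple alignment ('-' gaps);
    distances are computed column-wise on the given rows.
    """
    if len(reads) < 2:
        raise ValueError("need at least two reads")
    for r in reads:
        if not r.bases.replace("-", ""):
            raise ValueError(f"read {r.read_id!r} is empty")
    ids = tuple(r.read_id for r in reads)
    n = len(reads)
    d = np.zeros((n, n))
    if mode == "aligned":
        lens = {len(r.bases) for r in reads}
        if len(lens) != 1:
            raise ValueError("aligned mode requires equal-length rows")
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _aligned_distance(reads[i].bases,
                                                      reads[j].bases)
    elif mode == "pairwise":
        aligner = _make_aligner()
        for i in range(n):
            for j in range(i + 1, n):
                aln = aligner.align(reads[i].bases, reads[j].bases)[0]
                d[i, j] = d[j, i] = _aligned_distance(aln[0], aln[1])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceMatrix(ids, np.clip(d, 0.0, 1.0))


# ---------------------------------------------------------------------------
# complete-linkage OTU clustering

@dataclass(frozen=True)
class OtuTable:
    """Per-sample OTU counts at one clustering threshold."""

    counts: pd.DataFrame          # rows OTU ids, columns sample ids
    threshold: float
    clusters: tuple[frozenset, ...]   # member read ids per OTU

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    def sample_counts(self, sample: str) -> np.ndarray:
        c = self.counts[sample].to_numpy()
        return c[c > 0]


def cluster_complete_linkage(dm: DistanceMatrix, threshold: float,
                             sample_of: Optional[Mapping[str, str]] = None
                             ) -> OtuTable:
    """Agglomerative complete-linkage clustering cut at ``threshold``.

    Repeatedly merges the pair of clusters with the smallest complete-link
    (maximum pairwise) distance while that distance is <= threshold.  Ties
    are broken toward the lexicographically smallest (min-id, min-id) pair,
    making the result order-independent and deterministic.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    idx = {rid: k for k, rid in enumerate(dm.ids)}
    clusters: list[set[str]] = [{rid} for rid in sorted(dm.ids)]

    def link(a: set, b: set) -> float:
        return max(dm.d[idx[x], idx[y]] for x in a for y in b)

    while len(clusters) > 1:
        best = None
        best_key = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = link(clusters[i], clusters[j])
                if dist > threshold:
                    continue
                key = (dist, *sorted((min(clusters[i]), min(clusters[j]))))
                if best_key is None or key < best_key:
                    best, best_key = (i, j), key
        if best is None:
            break
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]

    clusters.sort(key=min)
    samples = (sorted(set(sample_of.values())) if sample_of
               else ["sample"])
    rows = []
    for c in clusters:
        row = dict.fromkeys(samples, 0)
        for rid in c:
            row[sample_of[rid] if sample_of else "sample"] += 1
        rows.append(row)
    counts = pd.DataFrame(rows, index=[f"OTU_{k + 1:04d}"
                                       for k in range(len(clusters))])
    return OtuTable(counts, threshold, tuple(frozenset(c) for c in clusters))


# ---------------------------------------------------------------------------
# alpha diversity

@dataclass(frozen=True)
class DiversitySummary:
    s_obs: int
    f1: int
    f2: int
    chao1: float
    shannon: float
    pielou: float


def chao1(counts: Sequence[int], bias_corrected: bool = False) -> float:
    """Chao1 richness from singletons (F1) and doubletons (F2).

    classic:         S_obs + F1^2 / (2 F2)
    bias-corrected:  S_obs + F1 (F1 - 1) / (2 (F2 + 1))

    The classic form is undefined at F2 = 0 with F1 > 0; it then falls back
    to the bias-corrected form with a warning.
    """
    c = np.asarray(counts)
    if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    c = c[c > 0]
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if not bias_corrected:
        if f2 > 0:
            return s_obs + f1 * f1 / (2.0 * f2)
        if f1 > 0:
            warnings.warn("no doubletons: classic Chao1 undefined, "
                          "using bias-corrected form", stacklevel=2)
        # fall through
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon_pielou(counts: Sequence[int],
                   base: float = math.e) -> tuple[float, float]:
    """Shannon diversity H and Pielou evenness J = H / log(S_obs).

    Natural log by default; J is defined as 0 for a single OTU.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    p = c / c.sum()
    h = float(-(p * (np.log(p) / math.log(base))).sum())
    j = h / (math.log(c.size) / math.log(base)) if c.size > 1 else 0.0
    return h, j


def rarefaction(counts: Sequence[int],
                depths: Sequence[int]) -> pd.DataFrame:
    """Exact expected OTU counts in random subsamples of the given depths.

    E[S(n)] = sum_i (1 - C(N - N_i, n) / C(N, n)) with N the total count —
    the hypergeometric closed form; computed in log space for stability.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    n_total = int(c.sum())
    rows = []
    for n in depths:
        if n > n_total:
            raise ValueError(f"depth {n} exceeds total count {n_total}")
        if n < 0:
            raise ValueError("depth must be non-negative")
        # log C(N - Ni, n) - log C(N, n); zero term when N - Ni < n
        keep = (n_total - c) >= n
        log_ratio = (gammaln(n_total - c[keep] + 1) - gammaln(n + 1)
                     - gammaln(n_total - c[keep] - n + 1)
                     - (gammaln(n_total + 1) - gammaln(n + 1)
                        - gammaln(n_total - n + 1)))
        expected = float(c.size - np.exp(log_ratio).sum())
        rows.append((n, expected))
    return pd.DataFrame(rows, columns=["depth", "expected_otus"])


def summarize(counts: Sequence[int],
              bias_corrected: bool = False) -> DiversitySummary:
    """Chao1 + Shannon + Pielou with the supporting tallies, in one shot."""
    c = np.asarray(counts)
    pos = c[c > 0]
    h, j = shannon_pielou(pos)
    return DiversitySummary(
        s_obs=int(pos.size),
        f1=int((pos == 1).sum()),
        f2=int((pos == 2).sum()),
        chao1=chao1(np.asarray(pos, dtype=np.int64),
                    bias_corrected=bias_corrected),
        shannon=h,
        pielou=j,
    )


def summary_frame(tables: Mapping[float, OtuTable],
                  bias_corrected: bool = False) -> pd.DataFrame:
    """Per-sample diversity summary across clustering thresholds.

    Rows are samples; columns are (threshold, index) pairs in the classic
    report layout: Chao1 / Shannon / Pielou at each distance.
    """
    cols = {}
    for t in sorted(tables):
        table = tables[t]
        for sample in table.counts.columns:
            s = summarize(table.sample_counts(sample).astype(np.int64),
                          bias_corrected=bias_corrected)
            cols.setdefault(sample, {}).update({
                (t, "chao1"): s.chao1,
                (t, "shannon"): s.shannon,
                (t, "pielou"): s.pielou,
            })
    frame = pd.DataFrame(cols).T
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["threshold", "index"])
    return frame.sort_index()
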