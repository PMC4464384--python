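"""Genome binning by coverage window + tetranucleotide composition, with
single-copy-marker QC and relative-abundance estimation.

A dominant community member shows up in an assembly as a cluster of contigs
at a characteristic fold-coverage; selecting a coverage window around that
cluster and then discarding compositional outliers (tetranucleotide
frequency, TNF) yields a draft genome bin.  Bin quality is scored against a
set of single-copy marker genes: completeness is the fraction of markers
present at all, redundancy the fraction of present markers seen more than
once.  The bin's share of the community follows from

    abundance% = 100 * mean_coverage * (bin_bp / completeness) / total_bp

i.e. coverage times the completeness-corrected genome size over the total
sequenced bases.

TNF vectors use reverse-complement canonicalization: each 4-mer is pooled
with its reverse complement, giving 136 classes (120 complementary pairs +
16 palindromes), which makes the vector strand-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import Contig, reverse_complement
from .synthetic import MarkerSet

# ---------------------------------------------------------------------------
# canonical tetranucleotides

def _build_canonical_table() -> tuple[np.ndarray, tuple[str, ...]]:
    bases = "ACGT"
    kmers = ["".join((bases[i >> 6 & 3], bases[i >> 4 & 3],
                      bases[i >> 2 & 3], bases[i & 3])) for i in range(256)]
    canon = [min(k, reverse_complement(k)) for k in kmers]
    classes = tuple(sorted(set(canon)))
    index = {c: j for j, c in enumerate(classes)}
    table = np.array([index[c] for c in canon], dtype=np.int64)
    return table, classes

_CANON_TABLE, TNF_CLASSES = _build_canonical_table()
N_TNF_CLASSES = len(TNF_CLASSES)          # 136

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def tnf(contig: Union[Contig, str]) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (length 136, sums to 1).

    Windows containing non-ACGT characters are skipped; a sequence with no
    valid window raises.
    """
    seq = contig.bases if isinstance(contig, Contig) else contig
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 bp")
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size - 3
    words = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in range(4):
        window = codes[off:off + n]
        words = words * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    words = words[valid]
    if words.size == 0:
        raise ValueError("no valid 4-mer window (all ambiguous)")
    counts = np.bincount(_CANON_TABLE[words], minlength=N_TNF_CLASSES)
    return counts / counts.sum()


def tnf_matrix(contigs: Sequence[Contig]) -> np.ndarray:
    return np.vstack([tnf(c) for c in contigs])


# ---------------------------------------------------------------------------
# bin container

@dataclass(frozen=True)
class GenomeBin:
    """A set of contigs treated as one draft genome."""

    contigs: tuple[Contig, ...]

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(c.contig_id for c in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def total_bp(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def mean_coverage(self) -> float:
        """Length-weighted mean fold-coverage of the members."""
        if not self.contigs:
            return 0.0
        w = sum(c.coverage * c.length for c in self.contigs)
        return w / self.total_bp


@dataclass(frozen=True)
class BinQc:
    completeness: float     # % of the marker set present at >= 1 copy
    redundancy: float       # % of present markers at > 1 copy
    marker_set_id: str


# ---------------------------------------------------------------------------
# selection and filtering

def select_by_coverage(contigs: Sequence[Contig],
                       min_len: int = 300,
                       cov_lo: float = 300.0,
                       cov_hi: float = 600.0,
                       strict_length: bool = False) -> list[Contig]:
    """Keep contigs inside a coverage window and above a length cutoff.

    Both coverage bounds are inclusive.  The length rule defaults to
    ``length >= min_len``; ``strict_length`` switches to a strict
    ``length > min_len``.
    """
    if not cov_lo < cov_hi:
        raise ValueError("cov_lo must be < cov_hi")
    keep_len = (lambda n: n > min_len) if strict_length else \
               (lambda n: n >= min_len)
    return [c for c in contigs
            if keep_len(c.length) and cov_lo <= c.coverage <= cov_hi]


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def robust_centroid(profiles: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Length-weighted component-wise median TNF profile."""
    return np.array([_weighted_median(profiles[:, j], lengths.astype(float))
                     for j in range(profiles.shape[1])])


def tnf_filter(candidates: Sequence[Contig],
               method: str = "centroid",
               threshold: float = 95.0,
               seed: int = 0,
               iterations: int = 1) -> GenomeBin:
    """Drop compositional outliers from a coverage-selected contig set.

    method="centroid" (default): compute the robust (length-weighted
    component-wise median) TNF centroid and retain contigs whose Euclidean
    TNF distance to it is <= the ``threshold``-th percentile of all
    distances; ``iterations`` controls how many centroid/filter passes run
    (one by default).

    method="kmeans": k-means on TNF vectors with k chosen by silhouette
    over 2..5; the cluster with the most base pairs is kept.
    """
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate contigs")
    profiles = tnf_matrix(candidates)
    lengths = np.array([c.length for c in candidates])

    if method == "centroid":
        keep = list(range(len(candidates)))
        for _ in range(iterations):
            centroid = robust_centroid(profiles[keep], lengths[keep])
            dist = np.linalg.norm(profiles[keep] - centroid, axis=1)
            cut = np.percentile(dist, threshold)
            keep = [k for k, d in zip(keep, dist) if d <= cut]
        return GenomeBin(tuple(candidates[k] for k in keep))

    if method == "kmeans":
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        best_labels = None
        best_sil = -np.inf
        for k in range(2, min(5, len(candidates) - 1) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(profiles)
            if len(set(labels)) < 2:
                continue
            sil = silhouette_score(profiles, labels)
            if sil > best_sil:
                best_sil, best_labels = sil, labels
        if best_labels is None:
            return GenomeBin(tuple(candidates))
        bp = {lab: int(lengths[best_labels == lab].sum())
              for lab in set(best_labels)}
        top = max(sorted(bp), key=bp.get)
        return GenomeBin(tuple(c for c, lab in zip(candidates, best_labels)
                               if lab == top))

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# marker QC and abundance

def score_bin(bin_or_hits: Union[GenomeBin, None],
              marker_hits: Union[pd.DataFrame, Mapping[str, int]],
              marker_set: MarkerSet) -> BinQc:
    """Completeness/redundancy of a bin from a marker-gene hit table.

    ``marker_hits`` maps marker_id -> copy count in the bin (a table with
    columns marker_id/copy_count is also accepted).  Markers outside the
    declared set are ignored.
    """
    if len(marker_set) == 0:
        raise ValueError("empty marker set")
    if isinstance(marker_hits, pd.DataFrame):
        counts = dict(zip(marker_hits["marker_id"],
                          marker_hits["copy_count"]))
    else:
        counts = dict(marker_hits)
    present = [m for m in marker_set.marker_ids if counts.get(m, 0) >= 1]
    multi = [m for m in present if counts[m] > 1]
    completeness = 100.0 * len(present) / len(marker_set)
    redundancy = 100.0 * len(multi) / len(present) if present else 0.0
    return BinQc(completeness, redundancy, marker_set.set_id)


def abundance_percent(mean_coverage: float,
                      bin_size_bp: float,
                      completeness: float,
                      total_sequenced_bp: float) -> float:
    """Relative abundance (%) of a draft genome in its metagenome.

    The bin size is first corrected to a full-genome estimate by dividing
    by completeness (a fraction in (0, 1]); coverage times genome size is
    the genome's share of the sequenced bases.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must lie in (0, 1]")
    if total_sequenced_bp <= 0:
        raise ValueError("total_sequenced_bp must be positive")
    return 100.0 * mean_coverage * (bin_size_bp / completeness) \
        / total_sequenced_bp


def estimate_abundance(bin: GenomeBin,
                       completeness: float,
                       total_sequenced_bp: float) -> float:
    """``abundance_percent`` evaluated on a bin's own coverage and size."""
    return abundance_percent(bin.mean_coverage, bin.total_bp,
                             completeness, total_sequenced_bp)
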