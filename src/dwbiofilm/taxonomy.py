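"""Naive-Bayes k-mer taxonomic classification with bootstrap confidence.

The classifier follows the classic ribosomal-sequence approach: a genus is
modelled by the probability that a training sequence of that genus contains
each k-mer ("word", k = 8 by default),

    P(w | genus) = (m(w) + 0.5) / (M + 1)

with m(w) the number of the genus's M training sequences containing w.  A
query read is scored per genus by the sum of log P over its *distinct*
words; confidence comes from bootstrap trials that each rescore a random
eighth of the words, and a read is reported at the deepest rank whose
bootstrap support reaches the confidence threshold (0.80 by convention).
Both orientations of the read are scored and the better one is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import SeqRead, reverse_complement
from .synthetic import RANKS

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def distinct_words(seq: str, k: int) -> np.ndarray:
    """Sorted distinct k-mer codes of a sequence; windows with non-ACGT
    characters are skipped."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    words = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in range(k):
        window = codes[off:off + n]
        words = words * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    return np.unique(words[valid])


Lineage = Mapping[str, str]


@dataclass(frozen=True)
class TaxModel:
    k: int
    genera: tuple[str, ...]
    log_p: np.ndarray                 # (n_genera, 4^k) log P(w | genus)
    lineages: Mapping[str, Lineage]   # genus -> rank -> name
    n_train: Mapping[str, int]        # genus -> M


@dataclass(frozen=True)
class TaxAssignment:
    """Per-rank taxon calls with bootstrap confidences for one read."""

    read_id: str
    lineage: Mapping[str, tuple[str, float]]   # rank -> (name, confidence)
    assigned_rank: Optional[str]               # deepest rank >= threshold

    def name_at(self, rank: str) -> Optional[str]:
        entry = self.lineage.get(rank)
        return entry[0] if entry else None

    def confidence_at(self, rank: str) -> float:
        entry = self.lineage.get(rank)
        return entry[1] if entry else 0.0


def parse_lineage(text: str) -> dict[str, str]:
    """'Bacteria;Proteobacteria;...;Genus' -> rank->name map."""
    names = [p.strip() for p in text.strip().split(";")]
    if len(names) != len(RANKS):
        raise ValueError(f"lineage must have {len(RANKS)} ranks "
                         f"({';'.join(RANKS)}): got {text!r}")
    return dict(zip(RANKS, names))


def train(references: Sequence[tuple[Union[str, Lineage], str]],
          k: int = 8) -> TaxModel:
    """Build a classification model from (lineage, sequence) pairs.

    Lineages may be ';'-joined strings or rank->name maps complete to
    genus.  Word size must lie in [6, 10].
    """
    if not 6 <= k <= 10:
        raise ValueError("word size k must lie in [6, 10]")
    if not references:
        raise ValueError("no training sequences")

    lineages: dict[str, dict[str, str]] = {}
    present: dict[str, list[np.ndarray]] = {}
    for lineage, seq in references:
        lin = parse_lineage(lineage) if isinstance(lineage, str) else dict(lineage)
        missing = [r for r in RANKS if not lin.get(r)]
        if missing:
            raise ValueError(f"lineage incomplete at ranks {missing}")
        genus = lin["genus"]
        if genus in lineages and lineages[genus] != lin:
            raise ValueError(f"conflicting lineages for genus {genus!r}")
        lineages[genus] = lin
        present.setdefault(genus, []).append(distinct_words(seq, k))

    genera = tuple(sorted(present))
    vocab = 4 ** k
    log_p = np.empty((len(genera), vocab), dtype=np.float32)
    n_train = {}
    for gi, genus in enumerate(genera):
        m = np.zeros(vocab, dtype=np.float64)
        for words in present[genus]:
            m[words] += 1.0
        big_m = len(present[genus])
        log_p[gi] = np.log((m + 0.5) / (big_m + 1.0))
        n_train[genus] = big_m
    return TaxModel(k, genera, log_p, lineages, n_train)


def train_from_fasta(path, k: int = 8) -> TaxModel:
    """Train from a FASTA whose headers carry 'domain;...;genus' lineages."""
    from .records import read_fasta

    # Biopython keeps only the first whitespace token as the id; lineages
    # are ';'-joined without spaces, so the id itself is the lineage.
    refs = [(rec.read_id, rec.bases) for rec in read_fasta(path)]
    return train(refs, k=k)


def classify(model: TaxModel, read: SeqRead,
             n_bootstrap: int = 100,
             seed: int = 0,
             threshold: float = 0.8) -> TaxAssignment:
    """Classify one read; see module docstring for the algorithm.

    Reads with no valid word (shorter than k or all-ambiguous) come back
    unclassified at every rank.
    """
    rng = np.random.default_rng(seed)
    fwd = distinct_words(read.bases, model.k)
    rev = distinct_words(reverse_complement(read.bases), model.k)
    if fwd.size == 0 and rev.size == 0:
        return TaxAssignment(read.read_id, {}, None)

    def full_score(words: np.ndarray) -> float:
        return float(model.log_p[:, words].sum(axis=1).max()) if words.size else -np.inf

    words = fwd if full_score(fwd) >= full_score(rev) else rev
    sub = model.log_p[:, words]                      # (G, W)
    best_genus = int(sub.sum(axis=1).argmax())

    w = words.size
    m = -(-w // 8)                                   # ceil(W / 8)
    idx = rng.integers(0, w, size=(n_bootstrap, m))
    trial_scores = sub[:, idx.ravel()].reshape(len(model.genera),
                                               n_bootstrap, m).sum(axis=2)
    winners = trial_scores.argmax(axis=0)            # (n_bootstrap,)

    best_lineage = model.lineages[model.genera[best_genus]]
    winner_lineages = [model.lineages[model.genera[g]] for g in winners]
    lineage: dict[str, tuple[str, float]] = {}
    assigned = None
    for rank in RANKS:
        name = best_lineage[rank]
        agree = sum(1 for lin in winner_lineages if lin[rank] == name)
        conf = agree / n_bootstrap
        lineage[rank] = (name, conf)
    for rank in RANKS:                               # deepest rank >= threshold
        if lineage[rank][1] >= threshold:
            assigned = rank
        else:
            break
    return TaxAssignment(read.read_id, lineage, assigned)


def classify_many(model: TaxModel, reads: Iterable[SeqRead],
                  n_bootstrap: int = 100, seed: int = 0,
                  threshold: float = 0.8) -> list[TaxAssignment]:
    """Classify reads with per-read seeds derived from one master seed."""
    rng = np.random.default_rng(seed)
    return [classify(model, r, n_bootstrap=n_bootstrap,
                     seed=int(rng.integers(0, 2**31)), threshold=threshold)
            for r in reads]


def summarize_ranks(assignments: Mapping[str, Sequence[TaxAssignment]],
                    rank: str,
                    threshold: float = 0.8,
                    top: Optional[int] = None) -> pd.DataFrame:
    """Per-sample relative abundances (%) of taxa at one rank.

    The denominator per sample is the number of reads confidently assigned
    at the domain rank (designated 100%); reads confident at domain but not
    at ``rank`` are pooled into an 'unclassified' row.  ``top`` keeps the N
    most abundant taxa (by mean across samples) plus 'unclassified'.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    cols = {}
    for sample, assigns in assignments.items():
        domain_reads = [a for a in assigns
                        if a.confidence_at("domain") >= threshold]
        tally: dict[str, int] = {}
        for a in domain_reads:
            if a.confidence_at(rank) >= threshold:
                tally[a.name_at(rank)] = tally.get(a.name_at(rank), 0) + 1
            else:
                tally["unclassified"] = tally.get("unclassified", 0) + 1
        denom = len(domain_reads)
        cols[sample] = {t: 100.0 * n / denom for t, n in tally.items()} \
            if denom else {}
    frame = pd.DataFrame(cols).fillna(0.0)
    frame = frame.sort_index()
    if top is not None:
        taxa = frame.drop(index="unclassified", errors="ignore")
        keep = taxa.mean(axis=1).nlargest(top).index.tolist()
        if "unclassified" in frame.index:
            keep.append("unclassified")
        frame = frame.loc[keep]
    return frame
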