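"""Short-read shotgun preparation: quality filtering, de-replication, and
merging of overlapping pairs into "tags".

A 100 bp paired library from ~180 bp inserts overlaps in the middle, so each
pair can be collapsed into one fragment-length tag; annotation of a 160-180
bp tag is markedly more reliable than of either 100 bp mate.  The filter and
de-replication rules are the standard early-Illumina ones: drop reads with
>10% ambiguous bases or >50% of bases under Q20, and keep one representative
per cluster of reads sharing their first 50 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .records import ReadPair, SeqRead, Tag, reverse_complement


@dataclass
class FilterReport:
    n_in: int = 0
    n_kept: int = 0
    n_dropped_n: int = 0
    n_dropped_quality: int = 0


def _fails(read: SeqRead, max_n_frac: float, low_q: int,
           max_lowq_frac: float) -> Optional[str]:
    n = len(read)
    if read.bases.count("N") > max_n_frac * n:
        return "n"
    if read.quality is None:
        raise ValueError(f"read {read.read_id!r} lacks qualities but the "
                         "low-quality rule needs them")
    if sum(q < low_q for q in read.quality) > max_lowq_frac * n:
        return "q"
    return None


def quality_filter(items: Sequence[Union[SeqRead, ReadPair]],
                   max_n_frac: float = 0.10,
                   low_q: int = 20,
                   max_lowq_frac: float = 0.50,
                   ) -> tuple[list, FilterReport]:
    """Discard reads with too many Ns or too many low-quality bases.

    Both cutoffs are strict: a read is discarded iff its N fraction is
    *greater than* ``max_n_frac`` or its fraction of bases below ``low_q``
    is *greater than* ``max_lowq_frac``; a pair is discarded when either
    mate fails.
    """
    kept = []
    report = FilterReport(n_in=len(items))
    for item in items:
        mates = (item.forward, item.reverse) if isinstance(item, ReadPair) \
            else (item,)
        verdicts = [_fails(m, max_n_frac, low_q, max_lowq_frac)
                    for m in mates]
        bad = next((v for v in verdicts if v), None)
        if bad == "n":
            report.n_dropped_n += 1
        elif bad == "q":
            report.n_dropped_quality += 1
        else:
            kept.append(item)
            report.n_kept += 1
    return kept, report


@dataclass
class DerepResult:
    representatives: list
    cluster_sizes: list[int]

    @property
    def n_in(self) -> int:
        return sum(self.cluster_sizes)


def dereplicate(items: Sequence[Union[SeqRead, ReadPair]],
                prefix_len: int = 50,
                both_mates: bool = False) -> DerepResult:
    """Collapse reads whose first ``prefix_len`` bases are identical.

    Clustering is by the forward mate's prefix (``both_mates`` concatenates
    both prefixes instead); the first-encountered read represents its
    cluster and output order follows first appearance, which makes the
    operation idempotent.
    """
    reps: dict[str, int] = {}
    out: list = []
    sizes: list[int] = []
    for item in items:
        if isinstance(item, ReadPair):
            key = item.forward.bases[:prefix_len]
            if both_mates:
                key += "|" + item.reverse.bases[:prefix_len]
        else:
            key = item.bases[:prefix_len]
        if key in reps:
            sizes[reps[key]] += 1
        else:
            reps[key] = len(out)
            out.append(item)
            sizes.append(1)
    return DerepResult(out, sizes)


@dataclass
class MergeReport:
    n_in: int = 0
    n_merged: int = 0
    n_unmerged: int = 0
    n_ambiguous: int = 0


def _merge_one(pair: ReadPair, min_overlap: int,
               max_mismatch_frac: float) -> Optional[Tag]:
    fwd = pair.forward
    rev = pair.reverse.reverse_complement()
    max_ov = min(len(fwd), len(rev))

    best: Optional[tuple[int, int]] = None   # (matches, overlap)
    tie = False
    for ov in range(min_overlap, max_ov + 1):
        a = fwd.bases[len(fwd) - ov:]
        b = rev.bases[:ov]
        matches = sum(x == y for x, y in zip(a, b))
        if (ov - matches) > max_mismatch_frac * ov:
            continue
        if best is None or matches > best[0]:
            best, tie = (matches, ov), False
        elif matches == best[0]:
            # equal match count: the longer overlap wins; overlaps are
            # scanned in increasing length so the incumbent is shorter
            best, tie = (matches, ov), False
    if best is None or tie:
        return None

    _, ov = best
    off = len(fwd) - ov
    bases = []
    quals = []
    support = []
    fq = fwd.quality or (0,) * len(fwd)
    rq = rev.quality or (0,) * len(rev)
    for i in range(off):
        bases.append(fwd.bases[i]); quals.append(fq[i]); support.append("f")
    for i in range(ov):
        bf, br = fwd.bases[off + i], rev.bases[i]
        qf, qr = fq[off + i], rq[i]
        if bf == br:
            bases.append(bf); quals.append(max(qf, qr))
        else:
            bases.append(bf if qf >= qr else br)
            quals.append(max(qf, qr))
        support.append("b")
    for i in range(ov, len(rev)):
        bases.append(rev.bases[i]); quals.append(rq[i]); support.append("r")
    tag_id = fwd.read_id.rsplit("/", 1)[0]
    return Tag(tag_id, "".join(bases), tuple(quals), "".join(support))


def merge_tags(pairs: Sequence[ReadPair],
               min_overlap: int = 10,
               max_mismatch_frac: float = 0.10,
               ) -> tuple[list[Tag], list[ReadPair], MergeReport]:
    """Merge read pairs into tags via their best 3' overlap.

    The reverse mate is reverse-complemented and slid against the forward
    mate; among overlaps of at least ``min_overlap`` bases with a mismatch
    fraction <= ``max_mismatch_frac`` the one with the most matching bases
    wins (longer overlap on ties).  Disagreeing bases take the
    higher-quality call; agreeing bases keep the higher of the two
    qualities.  Pairs with no admissible overlap are returned unmerged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    tags: list[Tag] = []
    unmerged: list[ReadPair] = []
    report = MergeReport(n_in=len(pairs))
    for pair in pairs:
        tag = _merge_one(pair, min_overlap, max_mismatch_frac)
        if tag is None:
            unmerged.append(pair)
            report.n_unmerged += 1
        else:
            tags.append(tag)
            report.n_merged += 1
    return tags, unmerged, report
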