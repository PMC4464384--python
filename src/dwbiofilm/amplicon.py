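"""Amplicon read preparation: demultiplexing, primer trimming, depth
normalization.

Pyrosequencing-era amplicon libraries carry a sample barcode and the forward
PCR primer at the 5' end of every read; classification and diversity
analysis want neither.  Depth is equalized across samples by taking the
first N reads of each sample in file order (N = 8,951 in the study design
this mirrors), since richness estimators are depth-sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import SampleBatch, SeqRead, reverse_complement

#: IUPAC degenerate nucleotide codes -> the set of plain bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: V3-V4 forward primer and the four-member reverse-primer cocktail used for
#: the 16S amplicon libraries this module targets.
FORWARD_PRIMER = "ACTCCTACGGGAGGCAGCAG"
REVERSE_PRIMERS = (
    "TACCRGGGTHTCTAATCC",
    "TACCAGAGTATCTAATTC",
    "CTACDSRGGTMTCTAATC",
    "TACNVGGGTATCTAATCC",
)


def iupac_match(pattern_base: str, base: str) -> bool:
    """True if ``base`` is one of the plain bases the IUPAC code matches."""
    return base in IUPAC.get(pattern_base.upper(), "")


def _mismatches(pattern: str, text: str) -> int:
    """Hamming-style mismatch count of an IUPAC pattern vs plain bases."""
    return sum(not iupac_match(p, b) for p, b in zip(pattern, text))


@dataclass
class DemuxResult:
    batches: dict[str, SampleBatch]
    unassigned: list[SeqRead] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(len(b) for b in self.batches.values())


def demultiplex(reads: Sequence[SeqRead],
                barcode_map: Mapping[str, str],
                max_mismatch: int = 0) -> DemuxResult:
    """Assign reads to samples by their leading barcode and strip it.

    A read is assigned only when exactly one barcode lies within
    ``max_mismatch`` of its prefix; ties and too-short reads go to the
    unassigned pile.  Every input read ends up in exactly one place.
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be unique")
    lens = {len(b) for b in barcodes}
    if len(lens) != 1:
        raise ValueError("barcodes must have equal length")
    blen = lens.pop()

    result = DemuxResult({s: SampleBatch(s) for s in barcode_map})
    for read in reads:
        if len(read) < blen:
            result.unassigned.append(read)
            continue
        prefix = read.bases[:blen]
        best: list[str] = []
        best_d = max_mismatch + 1
        for sample, bc in barcode_map.items():
            d = sum(a != b for a, b in zip(bc, prefix))
            if d < best_d:
                best, best_d = [sample], d
            elif d == best_d:
                best.append(sample)
        if len(best) == 1 and best_d <= max_mismatch:
            result.batches[best[0]].reads.append(read.slice(blen))
        else:
            result.unassigned.append(read)
    return result


@dataclass
class TrimReport:
    n_in: int = 0
    n_kept: int = 0
    n_no_forward: int = 0
    n_reverse_trimmed: int = 0


def _find_reverse_hit(bases: str, primer: str, tol: int) -> Optional[int]:
    """Rightmost start of the reverse-complemented primer in ``bases``."""
    rc = reverse_complement(primer)
    m = len(rc)
    for start in range(len(bases) - m, -1, -1):
        if _mismatches(rc, bases[start:start + m]) <= tol:
            return start
    return None


def trim_primers(batch: SampleBatch,
                 primer_fwd: str = FORWARD_PRIMER,
                 reverse_primer_set: Sequence[str] = REVERSE_PRIMERS,
                 mismatch_per_10bp: int = 1,
                 ) -> tuple[SampleBatch, TrimReport]:
    """Strip the forward primer (and any trailing reverse-primer match).

    The forward primer must match at the 5' end within 1 mismatch per 10
    primer bases (IUPAC-aware); reads without it are dropped and counted.
    Each reverse primer of the cocktail is searched as its reverse
    complement near the 3' end; the first (rightmost) hit is trimmed.
    """
    if not primer_fwd:
        raise ValueError("forward primer must be non-empty")
    report = TrimReport(n_in=len(batch))
    fwd_tol = (len(primer_fwd) * mismatch_per_10bp) // 10
    out = SampleBatch(batch.sample_id)
    for read in batch.reads:
        if len(read) < len(primer_fwd) or \
                _mismatches(primer_fwd, read.bases[:len(primer_fwd)]) > fwd_tol:
            report.n_no_forward += 1
            continue
        trimmed = read.slice(len(primer_fwd))
        best_cut = None
        for rp in reverse_primer_set:
            tol = (len(rp) * mismatch_per_10bp) // 10
            hit = _find_reverse_hit(trimmed.bases, rp, tol)
            if hit is not None and (best_cut is None or hit > best_cut):
                best_cut = hit
        if best_cut is not None:
            trimmed = trimmed.slice(0, best_cut)
            report.n_reverse_trimmed += 1
        out.reads.append(trimmed)
        report.n_kept += 1
    return out, report


def normalize_depth(batch: SampleBatch, n: int,
                    shuffle_seed: Optional[int] = None) -> SampleBatch:
    """Keep the first ``n`` reads of a sample (file order).

    With ``shuffle_seed`` set, a random subsample of size ``n`` is drawn
    instead (order of the survivors preserved).  Warns when the sample is
    shallower than ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(batch) < n:
        warnings.warn(f"sample {batch.sample_id!r} has only {len(batch)} "
                      f"reads (< {n}); keeping all", stacklevel=2)
        return SampleBatch(batch.sample_id, list(batch.reads))
    if shuffle_seed is None:
        return SampleBatch(batch.sample_id, list(batch.reads[:n]))
    rng = np.random.default_rng(shuffle_seed)
    keep = sorted(rng.choice(len(batch), size=n, replace=False))
    return SampleBatch(batch.sample_id, [batch.reads[i] for i in keep])
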