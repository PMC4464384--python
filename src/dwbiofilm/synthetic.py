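"""Synthetic community generator.

Everything downstream of sequencing in the pipeline — demultiplexing, OTU
clustering, taxonomic classification, read merging, binning and its QC — is
exercised against communities built here, for which the ground truth (read
origins, contig origins, marker locations, true abundances) is known exactly.

The generator states a world rather than fitting one:

* genomes are order-0 Markov (i.i.d.) DNA with a configurable GC content;
  distinct GC (>= 8% gaps by default) is what makes tetranucleotide
  composition separate genomes and k-mer profiles separate genera;
* single-copy marker genes are planted as labelled loci on each genome
  (no HMM/BLAST search is performed anywhere in the package);
* shotgun fragments are Normal-length inserts sequenced from both ends at a
  fixed read length, with i.i.d. substitution errors and Phred qualities
  drawn from Normal(35, 4) clipped to [2, 40];
* amplicons are barcode + forward primer + a genome-derived fragment whose
  length is Normal(length_mean, length_sd) truncated at >= 200 bp.

Indels, chimeras, homopolymer errors, plasmids and strain microdiversity are
deliberately absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import Contig, ReadPair, SeqRead, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Size of the essential-single-copy-gene-like default marker set.
DEFAULT_N_MARKERS = 105
DEFAULT_MARKER_LEN = 600


@dataclass(frozen=True)
class MarkerSet:
    """A named set of markers expected at exactly one copy per genome."""

    set_id: str
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError(f"marker set {self.set_id!r} has duplicate ids")

    def __len__(self) -> int:
        return len(self.marker_ids)


def escg_like_marker_set(n: int = DEFAULT_N_MARKERS,
                         set_id: str = "escg105") -> MarkerSet:
    """Marker set mimicking the 105-gene essential single-copy set."""
    return MarkerSet(set_id, tuple(f"escg_{i:03d}" for i in range(1, n + 1)))


@dataclass(frozen=True)
class ReferenceGenome:
    """A reference genome with taxonomy and planted single-copy marker loci.

    ``marker_loci`` are ``(marker_id, start, end)`` 0-based half-open
    intervals on ``sequence``; they must be in-bounds and non-overlapping.
    """

    genome_id: str
    sequence: str
    taxonomy: Mapping[str, str]
    marker_loci: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"genome {self.genome_id!r}: non-ACGT bases")
        last_end = -1
        for mid, start, end in sorted(self.marker_loci, key=lambda m: m[1]):
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"marker {mid!r} out of bounds")
            if start < last_end:
                raise ValueError(f"marker {mid!r} overlaps a previous locus")
            last_end = end

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CommunityDesign:
    """Abundance structure and sequencing parameters of a mock community."""

    abundances: Mapping[str, float]
    total_bases: int
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 20.0
    read_length: int = 100
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.abundances.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("abundances must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {vals.sum()}, not 1")
        if self.read_length > self.fragment_length_mean + 4 * self.fragment_length_sd:
            raise ValueError("read_length exceeds fragment mean + 4 sd")

    def fold_coverage(self, genome_lengths: Mapping[str, int]) -> dict[str, float]:
        """Expected fold-coverage per genome: abundance * total / length."""
        return {g: self.abundances[g] * self.total_bases / genome_lengths[g]
                for g in self.abundances}


# ---------------------------------------------------------------------------
# genome synthesis

def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. DNA with P(G)+P(C) = gc."""
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    idx = rng.choice(4, size=length, p=[at, gcp, gcp, at])
    return _BASES[idx].tobytes().decode()


def plant_markers(length: int, markers: MarkerSet,
                  marker_len: int = DEFAULT_MARKER_LEN
                  ) -> tuple[tuple[str, int, int], ...]:
    """Place marker loci evenly along a genome, one copy each."""
    n = len(markers)
    spacing = length // n
    if spacing <= marker_len:
        raise ValueError("genome too short for the requested marker set")
    pad = (spacing - marker_len) // 2
    return tuple((mid, i * spacing + pad, i * spacing + pad + marker_len)
                 for i, mid in enumerate(markers.marker_ids))


def simulate_genome(genome_id: str, length: int, gc: float,
                    taxonomy: Mapping[str, str],
                    rng: np.random.Generator,
                    markers: Optional[MarkerSet] = None,
                    marker_len: int = DEFAULT_MARKER_LEN) -> ReferenceGenome:
    seq = random_sequence(length, gc, rng)
    loci = plant_markers(length, markers, marker_len) if markers else ()
    return ReferenceGenome(genome_id, seq, dict(taxonomy), loci)


_DEFAULT_LINEAGES = [
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales",
     "Bradyrhizobiaceae", "Bradyrhizobium"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales",
     "Comamonadaceae", "Acidovorax"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
     "Pseudomonadaceae", "Pseudomonas"),
    ("Bacteria", "Bacteroidetes", "Sphingobacteriia", "Sphingobacteriales",
     "Chitinophagaceae", "Sediminibacterium"),
    ("Bacteria", "Nitrospirae", "Nitrospira", "Nitrospirales",
     "Nitrospiraceae", "Nitrospira"),
]
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def _lineage(i: int) -> dict[str, str]:
    return dict(zip(RANKS, _DEFAULT_LINEAGES[i % len(_DEFAULT_LINEAGES)]))


# Default five-genome drinking-water-biofilm-like community: one dominant
# genome in the 300-600x selection window (~28% of bases, ~450x), one
# contaminant just above the window edge (650x) whose coverage noise leaks a
# few contigs inside, and the rest well outside.
_DEFAULT_LENGTHS = (750_000, 600_000, 500_000, 800_000, 500_000)
_DEFAULT_COVERAGES = (450.0, 250.0, 650.0, 80.0, 700.0)
_DEFAULT_GC = (0.60, 0.40, 0.52, 0.32, 0.68)


def default_genomes(seed: int = 0,
                    markers: Optional[MarkerSet] = None,
                    lengths: Sequence[int] = _DEFAULT_LENGTHS,
                    gc: Sequence[float] = _DEFAULT_GC) -> list[ReferenceGenome]:
    if markers is None:
        markers = escg_like_marker_set()
    rng = np.random.default_rng(seed)
    return [simulate_genome(f"g{i + 1}", lengths[i], gc[i], _lineage(i), rng,
                            markers=markers)
            for i in range(len(lengths))]


def default_community(genomes: Sequence[ReferenceGenome],
                      coverages: Sequence[float] = _DEFAULT_COVERAGES,
                      seed: int = 0) -> CommunityDesign:
    """Community whose per-genome fold-coverages are ``coverages``.

    Abundances follow from coverage x length; total_bases is their sum, so
    the dominant genome lands at ~28% with the default geometry.
    """
    bases = np.array([c * len(g) for c, g in zip(coverages, genomes)])
    total = float(bases.sum())
    ab = {g.genome_id: float(b / total) for g, b in zip(genomes, bases)}
    # renormalize exactly
    s = sum(ab.values())
    ab = {k: v / s for k, v in ab.items()}
    return CommunityDesign(ab, int(round(total)), seed=seed)


# ---------------------------------------------------------------------------
# shotgun reads

def _apply_errors(seq: str, error_rate: float,
                  rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        # substitute with one of the three other bases
        cur = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def _qualities(n: int, rng: np.random.Generator) -> tuple[int, ...]:
    q = np.clip(np.rint(rng.normal(35.0, 4.0, size=n)), 2, 40)
    return tuple(int(x) for x in q)


def simulate_shotgun(community: CommunityDesign,
                     genomes: Sequence[ReferenceGenome]
                     ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate paired-end shotgun reads from a community.

    Fragments are drawn genome-by-genome in proportion to abundance until the
    sequenced bases reach ``total_bases`` (so the realized base count matches
    the design to within one pair).  Returns the pairs and a true-origin
    table with one row per pair: read_id, genome_id, fragment coordinates
    (0-based half-open, forward-strand), strand, and a truncation flag for
    fragments shorter than the read length.
    """
    by_id = {g.genome_id: g for g in genomes}
    missing = set(community.abundances) - set(by_id)
    if missing:
        raise KeyError(f"abundance given for unknown genome(s): {sorted(missing)}")

    rng = np.random.default_rng(community.seed)
    ids = sorted(community.abundances)
    probs = np.array([community.abundances[g] for g in ids])
    rl = community.read_length

    pairs: list[ReadPair] = []
    rows = []
    sequenced = 0
    i = 0
    while sequenced < community.total_bases:
        gid = ids[int(rng.choice(len(ids), p=probs))]
        g = by_id[gid]
        flen = int(round(rng.normal(community.fragment_length_mean,
                                    community.fragment_length_sd)))
        flen = max(rl // 2, min(flen, len(g)))
        truncated = flen < rl
        start = int(rng.integers(0, len(g) - flen + 1))
        frag = g.sequence[start:start + flen]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        fwd = _apply_errors(frag[:rl], community.error_rate, rng)
        rev = _apply_errors(reverse_complement(frag)[:rl],
                            community.error_rate, rng)
        rid = f"r{i:07d}"
        pairs.append(ReadPair(
            SeqRead(rid + "/1", fwd, _qualities(len(fwd), rng)),
            SeqRead(rid + "/2", rev, _qualities(len(rev), rng)),
            truncated=truncated))
        rows.append((rid, gid, start, start + flen, strand, truncated))
        sequenced += len(fwd) + len(rev)
        i += 1

    origin = pd.DataFrame(rows, columns=["read_id", "genome_id", "start",
                                         "end", "strand", "truncated"])
    return pairs, origin


# ---------------------------------------------------------------------------
# contigs

def simulate_contigs(community: CommunityDesign,
                     genomes: Sequence[ReferenceGenome],
                     frag_len_range: tuple[int, int] = (5_000, 15_000),
                     coverage_noise_sigma: float = 0.05,
                     ) -> tuple[list[Contig], pd.DataFrame]:
    """Tile each genome into contigs and assign noisy coverages.

    Bypasses assembly: contigs are consecutive genome substrings with random
    lengths in ``frag_len_range``; each contig's coverage is the genome's
    design fold-coverage times lognormal(0, sigma) noise.  Returns the
    contigs and an origin table (contig_id, genome_id, start, end).
    """
    if not genomes:
        raise ValueError("empty genome list")
    rng = np.random.default_rng(community.seed)
    lo, hi = frag_len_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad frag_len_range {frag_len_range}")
    cov = community.fold_coverage({g.genome_id: len(g) for g in genomes})

    contigs: list[Contig] = []
    rows = []
    for g in genomes:
        pos = 0
        k = 0
        while pos < len(g):
            length = int(rng.integers(lo, hi + 1))
            end = min(pos + length, len(g))
            noise = (1.0 if coverage_noise_sigma == 0
                     else float(rng.lognormal(0.0, coverage_noise_sigma)))
            cid = f"{g.genome_id}_c{k:05d}"
            contigs.append(Contig(cid, g.sequence[pos:end],
                                  cov[g.genome_id] * noise))
            rows.append((cid, g.genome_id, pos, end))
            pos = end
            k += 1
    origin = pd.DataFrame(rows, columns=["contig_id", "genome_id",
                                         "start", "end"])
    return contigs, origin


# ---------------------------------------------------------------------------
# amplicons

def simulate_amplicons(genomes: Sequence[ReferenceGenome],
                       n_per_sample: int,
                       barcode_map: Mapping[str, str],
                       primer_fwd: str,
                       primer_rev: str = "",
                       length_mean: float = 438.0,
                       length_sd: float = 16.0,
                       seed: int = 0,
                       composition: Optional[Mapping[str, Mapping[str, float]]] = None,
                       min_length: int = 200,
                       ) -> dict[str, list[SeqRead]]:
    """Single-end amplicon reads per sample: barcode + primer + fragment.

    Fragment lengths are Normal(length_mean, length_sd) truncated at
    ``min_length``; per-sample genome composition defaults to uniform.
    """
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcodes")
    if not primer_fwd:
        raise ValueError("forward primer must be non-empty")
    rng = np.random.default_rng(seed)
    gids = [g.genome_id for g in genomes]
    by_id = {g.genome_id: g for g in genomes}

    out: dict[str, list[SeqRead]] = {}
    for sample, barcode in barcode_map.items():
        if composition and sample in composition:
            comp = composition[sample]
            keys = sorted(comp)
            p = np.array([comp[k] for k in keys], dtype=float)
            p = p / p.sum()
        else:
            keys, p = gids, np.full(len(gids), 1.0 / len(gids))
        reads = []
        for i in range(n_per_sample):
            gid = keys[int(rng.choice(len(keys), p=p))]
            g = by_id[gid]
            flen = 0
            while flen < min_length:
                flen = int(round(rng.normal(length_mean, length_sd)))
            flen = min(flen, len(g))
            start = int(rng.integers(0, len(g) - flen + 1))
            frag = g.sequence[start:start + flen]
            reads.append(SeqRead(f"{sample}_a{i:06d}",
                                 barcode + primer_fwd + frag))
        out[sample] = reads
    return out


# ---------------------------------------------------------------------------
# marker hit tables

def emit_marker_hits(source: Union[ReferenceGenome, pd.DataFrame],
                     genomes: Sequence[ReferenceGenome],
                     marker_set: Optional[MarkerSet] = None) -> pd.DataFrame:
    """Count marker-locus copies fully contained in a bin's contigs.

    ``source`` is either a whole ``ReferenceGenome`` or a contig-origin
    table (columns genome_id, start, end) restricted to the bin's members.
    Returns a table (marker_id, copy_count); markers absent from the bin
    appear with count 0 when ``marker_set`` is given.
    """
    if isinstance(source, ReferenceGenome):
        intervals = [(source.genome_id, 0, len(source))]
    else:
        intervals = [(r.genome_id, int(r.start), int(r.end))
                     for r in source.itertuples(index=False)]

    counts: dict[str, int] = {}
    if marker_set is not None:
        counts.update({m: 0 for m in marker_set.marker_ids})
    loci = {g.genome_id: g.marker_loci for g in genomes}
    for gid, lo, hi in intervals:
        for mid, start, end in loci.get(gid, ()):
            if lo <= start and end <= hi:
                counts[mid] = counts.get(mid, 0) + 1
    return pd.DataFrame(sorted(counts.items()),
                        columns=["marker_id", "copy_count"])


# ---------------------------------------------------------------------------
# functional profiles

def simulate_profiles(n_groups: int = 3,
                      n_per_group: int = 10,
                      n_categories: int = 25,
                      reads_per_sample: int = 20_000,
                      seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster-structured functional-category count profiles.

    Each ecosystem group has its own Dirichlet-drawn category profile;
    samples are multinomial draws from their group profile, so within-group
    scatter is counting noise while between-group separation comes from the
    profiles themselves.  Returns (counts DataFrame, ecosystem labels).
    """
    rng = np.random.default_rng(seed)
    cats = [f"subsystem_{j:02d}" for j in range(n_categories)]
    rows, labels, index = [], [], []
    for gi in range(n_groups):
        p = rng.dirichlet(np.full(n_categories, 2.0))
        for si in range(n_per_group):
            rows.append(rng.multinomial(reads_per_sample, p))
            index.append(f"eco{gi}_s{si:02d}")
            labels.append(f"ecosystem_{gi}")
    counts = pd.DataFrame(rows, index=index, columns=cats)
    return counts, pd.Series(labels, index=index, name="ecosystem")
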