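"""Upstream-element enrichment and windowed k-mer over-representation.

tRNA genes are transcribed by RNA polymerase III; conserved elements in
the ~60 bp upstream of the mature-tRNA start (a T-rich stretch near -53,
a TATA-like box near -42, a second T-rich stretch near -30 and the pol
III transcription start element near -13) modulate expression. Two
analyses ask whether these elements co-occur with deletion phenotypes:

* anchored-element enrichment — does a phenotype class carry an element
  (IUPAC consensus within a tolerance window around its anchor) more
  often than expected by hypergeometric chance across the library?
* windowed k-mer scan — slide a 9 bp window along the upstream region
  and, per window, test every exact 4-8 bp k-mer seen in at least two
  foreground sequences for over-representation against a background set
  (one-sided Fisher), reporting the minimum E-value motif per window
  (E = p times the number of k-mers tested in that window).

Coordinates: position 0 is the first base of the mature tRNA; upstream
positions are negative, so position -k of an L-long flank is sequence
offset L - k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .simulate import _IUPAC_SETS

__all__ = [
    "FlankSet",
    "MotifElement",
    "DEFAULT_ELEMENTS",
    "EnrichmentResult",
    "ScanResult",
    "read_flanks",
    "match_element",
    "element_enrichment",
    "windowed_kmer_scan",
]


@dataclass
class FlankSet:
    """Upstream flanks, right-aligned so every sequence ends at -1."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"non-ACGT/N characters {sorted(bad)} in flank of {gene}"
                )
            self.sequences[gene] = seq.upper()

    @property
    def genes(self) -> list[str]:
        return list(self.sequences)

    def window(self, gene: str, start: int, length: int) -> str | None:
        """Sub-sequence covering upstream positions [start, start+length)
        (start negative); None when the flank does not cover it."""
        seq = self.sequences[gene]
        L = len(seq)
        lo = L + start
        hi = lo + length
        if lo < 0 or hi > L or start + length > 0:
            return None
        return seq[lo:hi]


@dataclass(frozen=True)
class MotifElement:
    """IUPAC consensus anchored at an upstream position, with a +/- bp
    tolerance window on the match start."""

    id: str
    consensus: str
    anchor: int
    tolerance: int = 4

    def __post_init__(self) -> None:
        if self.anchor >= 0:
            raise ValueError("anchor must be a negative (upstream) position")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(_IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC symbols {sorted(bad)} in consensus")


#: Default consensus stand-ins for the four conserved upstream elements
#: (T-rich at -53 and -30, TATA-like at -42, pol III TSS at -13). The
#: published definitions are positional matrices; these short IUPAC
#: consensi are configurable placeholders capturing their cores.
DEFAULT_ELEMENTS = (
    MotifElement("t_rich_-53", "TTTT", -53),
    MotifElement("tata_-42", "TATAWA", -42),
    MotifElement("t_rich_-30", "TTTT", -30),
    MotifElement("tss_-13", "YYCAA", -13),
)


@dataclass(frozen=True)
class EnrichmentResult:
    element_id: str
    gene_class: str
    N: int
    K: int
    n: int
    k: int
    p: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p))


@dataclass(frozen=True)
class ScanResult:
    window_start: int
    window_len: int
    best_motif: str | None
    fg_hits: int
    bg_hits: int
    p: float
    e_value: float
    n_tested: int
    available: bool = True

    @property
    def log10_e(self) -> float:
        return float(np.log10(self.e_value)) if self.e_value > 0 else -np.inf


def read_flanks(fasta_path, flank_len: int | None = None) -> FlankSet:
    """Read upstream flanks from FASTA (header word 1 = gene id).

    Sequences are right-aligned to position -1: a record shorter than
    ``flank_len`` simply does not cover the most distal positions, and
    queries there report unavailable.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gene = record.id
        if gene in sequences:
            raise ValueError(f"duplicate gene id {gene!r} in {fasta_path}")
        seq = str(record.seq)
        if flank_len is not None and len(seq) > flank_len:
            seq = seq[-flank_len:]
        sequences[gene] = seq
    return FlankSet(sequences)


def iupac_match(pattern: str, text: str) -> bool:
    """Exact-length IUPAC match of pattern against text."""
    if len(pattern) != len(text):
        return False
    return all(t in _IUPAC_SETS[p] for p, t in zip(pattern.upper(), text.upper()))


def match_element(
    flanks: FlankSet, gene: str, element: MotifElement
) -> tuple[bool, int | None] | None:
    """Match an anchored element in one gene's flank.

    Returns (matched, leftmost match position) when the tolerance window
    is fully covered by the flank, or None (unavailable) otherwise. Match
    positions are upstream coordinates of the consensus start.
    """
    m = len(element.consensus)
    lo = element.anchor - element.tolerance
    hi = element.anchor + element.tolerance
    # entire window of candidate starts must be readable
    if flanks.window(gene, lo, (hi - lo) + m) is None:
        return None
    for start in range(lo, hi + 1):
        text = flanks.window(gene, start, m)
        if text is not None and iupac_match(element.consensus, text):
            return True, start
    return False, None


def element_enrichment(
    flanks: FlankSet,
    class_membership: dict[str, str],
    elements: tuple[MotifElement, ...] = DEFAULT_ELEMENTS,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each element in each phenotype class.

    Universe per element: genes with a class label whose flank covers the
    element's window (N); carriers K are the matching genes; a class of
    size n containing k carriers scores the upper tail P(X >= k). Output
    one row per element x class with -log10 p.
    """
    classes = sorted(set(class_membership.values()))
    if not class_membership:
        raise ValueError("empty class membership")
    rows = []
    for element in elements:
        universe = []
        carriers = set()
        for gene in flanks.genes:
            if gene not in class_membership:
                continue
            res = match_element(flanks, gene, element)
            if res is None:
                continue
            universe.append(gene)
            if res[0]:
                carriers.add(gene)
        N = len(universe)
        if N == 0:
            raise ValueError(f"empty universe for element {element.id}")
        K = len(carriers)
        for cls in classes:
            members = [g for g in universe if class_membership[g] == cls]
            n = len(members)
            if n == 0:
                continue
            k = sum(g in carriers for g in members)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            p = min(max(p, np.finfo(float).tiny), 1.0)
            rows.append(
                {
                    "element_id": element.id,
                    "gene_class": cls,
                    "N": N,
                    "K": K,
                    "n": n,
                    "k": k,
                    "p": p,
                    "neg_log10_p": -np.log10(p),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScanConfig:
    """Windowed-scan settings. ``step`` defaults to the window size
    (non-overlapping tiles); overlapping windows inflate the family of
    tests without a matching correction and are opt-in."""

    window: int = 9
    kmin: int = 4
    kmax: int = 8
    start: int = -100
    stop: int = -1
    min_fg_support: int = 2
    step: int | None = None


def _window_kmers(seqs: list[str], kmin: int, kmax: int) -> dict[str, int]:
    """Count, per k-mer, the number of sequences containing it."""
    counts: dict[str, int] = {}
    for seq in seqs:
        seen = set()
        for k in range(kmin, kmax + 1):
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    seen.add(kmer)
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def windowed_kmer_scan(
    fg: FlankSet,
    bg: FlankSet,
    config: ScanConfig | None = None,
) -> list[ScanResult]:
    """Scan 9 bp windows for k-mers over-represented in the foreground.

    For each window start, every exact k-mer (kmin..kmax) present in at
    least ``min_fg_support`` foreground window sub-sequences is scored by
    a one-sided Fisher exact test on presence/absence (fg vs bg); its
    E-value is the Fisher p times the number of k-mers tested in that
    window. The minimum-E motif per window is reported. Windows covered
    by no sequence in either set are marked unavailable.
    """
    if config is None:
        config = ScanConfig()
    overlap = set(fg.genes) & set(bg.genes)
    if overlap:
        raise ValueError(f"foreground and background overlap: {sorted(overlap)[:3]}")
    step = config.step or config.window
    results = []
    for start in range(config.start, config.stop - config.window + 2, step):
        fg_windows = [
            w for g in fg.genes if (w := fg.window(g, start, config.window))
        ]
        bg_windows = [
            w for g in bg.genes if (w := bg.window(g, start, config.window))
        ]
        if not fg_windows or not bg_windows:
            results.append(
                ScanResult(start, config.window, None, 0, 0, 1.0, 1.0, 0, False)
            )
            continue
        fg_counts = _window_kmers(fg_windows, config.kmin, config.kmax)
        candidates = {
            kmer: c for kmer, c in fg_counts.items() if c >= config.min_fg_support
        }
        if not candidates:
            results.append(
                ScanResult(start, config.window, None, 0, 0, 1.0, 1.0, 0, True)
            )
            continue
        bg_counts = _window_kmers(bg_windows, config.kmin, config.kmax)
        n_tested = len(candidates)
        best = None
        for kmer in sorted(candidates):  # sorted => deterministic tie-break
            a = candidates[kmer]
            b = bg_counts.get(kmer, 0)
            table = [
                [a, len(fg_windows) - a],
                [b, len(bg_windows) - b],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            if best is None or p < best[1]:
                best = (kmer, float(p), a, b)
        kmer, p, a, b = best
        e_value = min(p * n_tested, float(n_tested))
        results.append(
            ScanResult(start, config.window, kmer, a, b, p, e_value, n_tested, True)
        )
    return results


def scan_to_frame(results: list[ScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "window_start": r.window_start,
                "window_len": r.window_len,
                "best_motif": r.best_motif,
                "fg_hits": r.fg_hits,
                "bg_hits": r.bg_hits,
                "p": r.p,
                "e_value": r.e_value,
                "log10_e": r.log10_e if r.best_motif else np.nan,
                "available": r.available,
            }
            for r in results
        ]
    )
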