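"""Condition-specific TF binding, peak annotation, and motif enrichment.

Stage 2. Peaks specific to one culture condition are defined by binary
non-overlap between the two conditions' peak sets. Peaks are annotated
against promoter windows (TSS +/- w, strand-aware TSS) and a caller-supplied
enhancer BED with precedence promoter > enhancer > intergenic. Known-motif
enrichment follows the HOMER recipe: log-odds PWM scanning of both strands
at a fraction-of-maximum threshold, then an upper-tail hypergeometric test
of hit-sequence counts in target vs background sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import round_half_up
from .intervals import GenomicInterval, PeakSet, overlap_pairs, overlapping_indices
from .io import BASES, PWM

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_PROMOTER_WINDOW = 2_000
DEFAULT_MAX_DIST = 100_000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def promoter_windows(genes: pd.DataFrame, window: int = DEFAULT_PROMOTER_WINDOW) -> PeakSet:
    """TSS +/- window intervals, one per gene, clipped at zero."""
    ivs = []
    for row in genes.itertuples():
        start = max(0, int(row.tss) - window)
        ivs.append(
            GenomicInterval(row.chrom, start, int(row.tss) + window + 1,
                            name=str(row.gene_id))
        )
    return PeakSet("promoters", ivs)


@dataclass
class AnnotationSet:
    """Promoter windows plus enhancer intervals, precedence promoter first."""

    promoters: PeakSet
    enhancers: PeakSet
    promoter_window: int = DEFAULT_PROMOTER_WINDOW

    @classmethod
    def from_genes(
        cls, genes: pd.DataFrame, enhancers: PeakSet,
        window: int = DEFAULT_PROMOTER_WINDOW,
    ) -> "AnnotationSet":
        return cls(promoter_windows(genes, window), enhancers, window)


def condition_specific_peaks(
    a: PeakSet, b: PeakSet, min_bp: int = 1
) -> dict[str, PeakSet]:
    """Split peaks into a-specific, b-specific and shared (from a's side).

    a_specific holds peaks of ``a`` overlapping no peak of ``b``; shared is
    its complement within ``a``, so ``|a_specific| + |shared| == |a|``.
    """
    hit_a = overlapping_indices(a, b, min_bp=min_bp)
    hit_b = overlapping_indices(b, a, min_bp=min_bp)
    return {
        "a_specific": PeakSet(
            f"{a.name}_specific",
            [iv for i, iv in enumerate(a) if i not in hit_a],
        ),
        "b_specific": PeakSet(
            f"{b.name}_specific",
            [iv for i, iv in enumerate(b) if i not in hit_b],
        ),
        "shared": PeakSet(
            "shared", [iv for i, iv in enumerate(a) if i in hit_a]
        ),
    }


def genomic_distribution(
    peaks: PeakSet, ann: AnnotationSet
) -> dict[str, float]:
    """Category fractions with precedence promoter > enhancer > intergenic.

    Also reports the combined promoter-or-enhancer percentage (half-up,
    two decimals) alongside raw counts.
    """
    in_prom = overlapping_indices(peaks, ann.promoters)
    in_enh = overlapping_indices(peaks, ann.enhancers) - in_prom
    n = len(peaks)
    n_prom, n_enh = len(in_prom), len(in_enh)
    n_inter = n - n_prom - n_enh
    if n == 0:
        raise ZeroDivisionError("empty peak set")
    combined = 100.0 * (n_prom + n_enh) / n
    return {
        "n": n,
        "n_promoter": n_prom,
        "n_enhancer": n_enh,
        "n_intergenic": n_inter,
        "frac_promoter": n_prom / n,
        "frac_enhancer": n_enh / n,
        "frac_intergenic": n_inter / n,
        "percent_promoter_or_enhancer": round_half_up(combined, 2),
        "percent_promoter_or_enhancer_raw": combined,
    }


def _tss_distance(iv: GenomicInterval, tss: int) -> int:
    """Distance from a TSS to an interval; 0 when the TSS lies inside."""
    return max(iv.start - tss, tss - (iv.end - 1), 0)


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: pd.DataFrame,
    ann: AnnotationSet,
    max_dist: int = DEFAULT_MAX_DIST,
) -> tuple[dict[int, str], set[str]]:
    """Map each peak to its target gene; return mapping and target-gene set.

    A peak overlapping a promoter window maps to that gene (nearest TSS, ties
    to the lexicographically smaller gene_id); otherwise the nearest TSS
    within ``max_dist`` wins under the same tie rule; farther peaks stay
    unassigned.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for row in genes.itertuples():
        by_chrom.setdefault(row.chrom, []).append((int(row.tss), str(row.gene_id)))
    prom_pairs = overlap_pairs(peaks, ann.promoters)
    prom_genes: dict[int, set[str]] = {}
    for i, j in prom_pairs:
        g = ann.promoters[j].name
        if g is not None:
            prom_genes.setdefault(i, set()).add(g)
    tss_of = {str(r.gene_id): int(r.tss) for r in genes.itertuples()}

    mapping: dict[int, str] = {}
    for i, iv in enumerate(peaks):
        if i in prom_genes:
            best = min(
                prom_genes[i], key=lambda g: (_tss_distance(iv, tss_of[g]), g)
            )
            mapping[i] = best
            continue
        candidates = by_chrom.get(iv.chrom, [])
        best_gene, best_dist = None, max_dist + 1
        for tss, gid in candidates:
            d = _tss_distance(iv, tss)
            if d < best_dist or (d == best_dist and best_gene and gid < best_gene):
                best_gene, best_dist = gid, d
        if best_gene is not None and best_dist <= max_dist:
            mapping[i] = best_gene
    return mapping, set(mapping.values())


# ---------------------------------------------------------------------------
# PWM scanning and enrichment
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def scan_pwm(
    seq: str, pwm: PWM, frac_of_max: float = 0.8
) -> list[tuple[int, str]]:
    """Log-odds scan of both strands; hits at >= frac_of_max * max score.

    Returns (offset, strand) pairs; offsets are 0-based positions of the
    match on the forward sequence for both strands. Windows containing N are
    skipped.
    """
    if not 0 < frac_of_max <= 1:
        raise ValueError("frac_of_max must be in (0, 1]")
    pwm.validate()
    L = len(pwm)
    seq = seq.upper()
    if len(seq) < L:
        return []
    lom = np.log2(np.maximum(pwm.probs, 1e-12) / pwm.background)  # (L, 4)
    # pad a sentinel row so N (index 4) poisons any window containing it
    lom_pad = np.vstack([lom.T, np.full(L, -np.inf)])  # (5, L)
    threshold = frac_of_max * pwm.max_score()

    hits: list[tuple[int, str]] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        enc = _encode(s)
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = lom_pad[windows, np.arange(L)].sum(axis=1)
        for off in np.flatnonzero(scores >= threshold - 1e-9):
            pos = int(off) if strand == "+" else len(seq) - L - int(off)
            hits.append((pos, strand))
    return sorted(hits)


def hypergeom_upper_tail(k: int, n_draws: int, k_total: int, population: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population, k_total, n_draws)."""
    return float(hypergeom.sf(k - 1, population, k_total, n_draws))


def motif_enrichment(
    target: Sequence[str],
    background: Sequence[str],
    pwm: PWM,
    frac_of_max: float = 0.8,
) -> dict[str, float]:
    """HOMER-style known-motif enrichment between two sequence sets.

    k_t / k_b count sequences with >= 1 hit; p is the upper-tail
    hypergeometric probability of >= k_t hit sequences among the n_t target
    draws from the pooled population.
    """
    if not target or not background:
        raise ValueError("both sequence sets must be non-empty")
    k_t = sum(bool(scan_pwm(s, pwm, frac_of_max)) for s in target)
    k_b = sum(bool(scan_pwm(s, pwm, frac_of_max)) for s in background)
    n_t, n_b = len(target), len(background)
    p = hypergeom_upper_tail(k_t, n_t, k_t + k_b, n_t + n_b)
    return {"k_t": k_t, "n_t": n_t, "k_b": k_b, "n_b": n_b, "p": p}


def motif_enrichment_table(
    target: Sequence[str],
    background: Sequence[str],
    pwms: Sequence[PWM],
    frac_of_max: float = 0.8,
) -> pd.DataFrame:
    """Enrichment across several motifs with Benjamini-Hochberg q-values."""
    rows = [
        {"motif": pwm.name, **motif_enrichment(target, background, pwm, frac_of_max)}
        for pwm in pwms
    ]
    df = pd.DataFrame(rows)
    p = df["p"].to_numpy()
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    df["q"] = np.minimum(q, 1.0)
    return df


def overlap_enrichment_test(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> dict[str, float]:
    """Upper-tail hypergeometric test for the overlap of two gene sets."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    n_overlap = len(set_a & set_b)
    p = hypergeom_upper_tail(n_overlap, len(set_a), len(set_b), len(universe))
    return {"n_a": len(set_a), "n_b": len(set_b), "n_universe": len(universe),
            "n_overlap": n_overlap, "p": p}
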