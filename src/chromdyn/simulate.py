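"""Synthetic-data generation with planted ground truth for every stage.

Emulates the downstream products of an ESC culture-transition study — per-
time-point ATAC peak calls over a 6-point time course (days 0..15 in steps
of 3), condition-specific TF ChIP peaks with an embedded binding motif,
wild-type/knockout expression trajectories drawn from the five canonical
response templates, and chromatin loops with replicate counts plus binned
contact matrices carrying compartment structure and loop-pixel enrichment —
on toy chromosomes small enough to analyse in seconds. Every record is
aligned one-to-one with a ground-truth table so each downstream stage can be
scored against what was planted.

All randomness flows from ``SimConfig.seed`` through per-generator
substreams; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .expression import CONDITION_ORDER, EXPRESSION_TEMPLATES
from .intervals import GenomicInterval, PeakSet
from .io import BASES, PWM
from .loops import LoopRecord

# substream ids so the four generators draw independent randomness
_STREAM_TIMECOURSE_FWD = 11
_STREAM_TIMECOURSE_REV = 12
_STREAM_BINDING = 21
_STREAM_EXPRESSION = 31
_STREAM_LOOPS = 41


class CapacityError(ValueError):
    """Requested more features than the toy genome can hold."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the study design where it states one (six time points,
    three days apart; asymmetric TF peak sets; five expression patterns in
    realistic cluster proportions; more decreased than increased loops)
    and otherwise sit at desk-scale values a practitioner would call
    realistic for a smoke-testable genome.
    """

    seed: int = 0

    # --- accessibility time course ---
    n_timepoints: int = 6
    n_peaks: int = 5_000
    flicker_rate: float = 0.05
    class_mix: Optional[dict[str, float]] = None
    peak_width: int = 300
    peak_spacing: int = 800
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000, "chr3": 1_000_000}
    )

    # --- TF binding / annotation / motif ---
    binding_genome: dict[str, int] = field(
        default_factory=lambda: {"chrA": 3_000_000, "chrB": 3_000_000}
    )
    n_tf_peaks: int = 800
    n_tf_shared: int = 300
    tf_peak_width: int = 200
    frac_specific_promoter: float = 0.25
    frac_specific_enhancer: float = 0.19
    n_decoy_genes: int = 100
    n_decoy_enhancers: int = 100
    n_background_seqs: int = 500
    motif_embed_rate: float = 0.8
    promoter_window: int = 2_000

    # --- expression ---
    n_genes: int = 1_000
    expr_dispersion: float = 0.05
    expr_replicates: int = 2
    cluster_mix: Optional[dict[str, float]] = None
    n_de_up: int = 300
    n_de_down: int = 250

    # --- loops & matrices ---
    n_loops: int = 2_000
    replicates: int = 3
    nb_dispersion: float = 0.1
    frac_loops_down: float = 0.20
    frac_loops_up: float = 0.09
    loop_log2fc_down: tuple = (-3.0, -1.0)
    loop_log2fc_up: tuple = (1.0, 2.5)
    loop_mean_log: float = 3.5
    loop_mean_sigma: float = 0.8
    frac_low_confidence: float = 0.05
    frac_ep: float = 0.5
    frac_tf_of_ep: float = 0.6
    n_bins: int = 200
    resolution: int = 25_000
    matrix_depth: float = 30.0
    decay_exponent: float = 1.0
    compartment_strength: float = 0.6
    compartment_block: int = 25
    switch_frac: float = 0.05
    loop_enrichment: float = 3.0

    def default_class_mix(self) -> dict[str, float]:
        T = self.n_timepoints
        mix = {"PO": 0.35, "never": 0.15}
        per = 0.25 / (T - 1)
        for k in range(1, T):
            mix[f"CO_{k}"] = per
            mix[f"OC_{k}"] = per
        return mix

    def validate(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if not 0 <= self.flicker_rate < 0.5:
            raise ValueError("flicker_rate must lie in [0, 0.5)")
        mix = self.class_mix or self.default_class_mix()
        if not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must sum to 1")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2.

    The gamma-mixed-Poisson parametrization: dispersion -> 0 recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _place_loci(
    rng: np.random.Generator,
    genome: dict[str, int],
    n: int,
    width: int,
    spacing: int,
    margin: int = 1_000,
) -> list[tuple[str, int]]:
    """Pick n non-overlapping (chrom, start) slots on a slot grid."""
    slots = []
    for chrom, length in genome.items():
        n_slots = max(0, (length - width - 2 * margin) // spacing + 1)
        slots.extend((chrom, margin + i * spacing) for i in range(n_slots))
    if n > len(slots):
        raise CapacityError(
            f"requested {n} loci but the toy genome holds only {len(slots)}"
        )
    chosen = rng.choice(len(slots), size=n, replace=False)
    return sorted(
        (slots[i] for i in chosen), key=lambda cs: (cs[0], cs[1])
    )


# ---------------------------------------------------------------------------
# 1. time-course peaks
# ---------------------------------------------------------------------------


def _ideal_vector(cls: str, T: int) -> np.ndarray:
    if cls == "PO":
        return np.ones(T, dtype=bool)
    if cls == "never":
        return np.zeros(T, dtype=bool)
    name, k = cls.split("_")
    k = int(k)
    v = np.zeros(T, dtype=bool)
    if name == "CO":
        v[k:] = True
    elif name == "OC":
        v[:k] = True
    else:
        raise ValueError(f"unknown class {cls!r}")
    return v


@dataclass
class TimecourseSim:
    peak_sets: list[PeakSet]
    truth: pd.DataFrame  # chrom,start,end,true_class,ideal,observed


def simulate_timecourse_peaks(cfg: SimConfig, direction: str = "fwd") -> TimecourseSim:
    """Per-time-point peak calls with planted temporal classes.

    Each locus draws a class from the mix; its ideal open vector follows the
    class archetype and each bit is flipped independently at flicker_rate.
    A locus appears in the peak set of time t iff its observed bit is 1.
    """
    cfg.validate()
    stream = _STREAM_TIMECOURSE_FWD if direction == "fwd" else _STREAM_TIMECOURSE_REV
    rng = cfg.rng(stream)
    T = cfg.n_timepoints
    mix = cfg.class_mix or cfg.default_class_mix()
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    loci = _place_loci(rng, cfg.genome, cfg.n_peaks, cfg.peak_width, cfg.peak_spacing)
    assigned = rng.choice(len(classes), size=cfg.n_peaks, p=probs)
    ideal = np.vstack([_ideal_vector(classes[a], T) for a in assigned])
    flips = rng.random((cfg.n_peaks, T)) < cfg.flicker_rate
    observed = ideal ^ flips

    day = lambda t: f"d{3 * t}"
    peak_sets = []
    for t in range(T):
        ivs = [
            GenomicInterval(c, s, s + cfg.peak_width)
            for (c, s), present in zip(loci, observed[:, t])
            if present
        ]
        peak_sets.append(PeakSet(day(t), ivs))
    bits = lambda row: "".join("1" if b else "0" for b in row)
    truth = pd.DataFrame(
        {
            "chrom": [c for c, _ in loci],
            "start": [s for _, s in loci],
            "end": [s + cfg.peak_width for _, s in loci],
            "true_class": [classes[a] for a in assigned],
            "ideal": [bits(r) for r in ideal],
            "observed": [bits(r) for r in observed],
        }
    )
    return TimecourseSim(peak_sets, truth)


# ---------------------------------------------------------------------------
# 2. annotation, TF binding, motif
# ---------------------------------------------------------------------------

#: planted TF motif (TEA-domain-like consensus GGAATGTG)
_MOTIF_CONSENSUS = "GGAATGTG"


def default_pwm(name: str = "TEAD_like", strength: float = 0.85) -> PWM:
    """A sharply peaked PWM whose consensus is the planted motif."""
    rows = []
    off = (1.0 - strength) / 3.0
    for base in _MOTIF_CONSENSUS:
        row = [off] * 4
        row[BASES.index(base)] = strength
        rows.append(row)
    return PWM(name, np.array(rows))


@dataclass
class BindingSim:
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    enhancers: PeakSet
    tf_a: PeakSet  # ground-state condition (superset)
    tf_b: PeakSet  # serum condition (subset of tf_a)
    fasta: dict[str, str]
    pwm: PWM
    background: PeakSet  # unbound windows for enrichment background
    truth: pd.DataFrame  # per-A-peak category + motif flag


def simulate_annotation_and_binding(cfg: SimConfig) -> BindingSim:
    """TF peak sets (B a strict subset of A), annotation and motif planting.

    A-specific peaks are split into promoter/enhancer/intergenic categories
    at the configured fractions (deterministic counts); a gene TSS or an
    enhancer interval is created under each categorised peak, with decoy
    genes and enhancers elsewhere. The toy genome sequence is uniform random
    ACGT with the motif consensus written into each bound (A) peak with
    probability motif_embed_rate.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_BINDING)
    width = cfg.tf_peak_width
    spacing = 6_000
    loci = _place_loci(rng, cfg.binding_genome, cfg.n_tf_peaks, width, spacing)
    tf_a = PeakSet("tf_a", [GenomicInterval(c, s, s + width) for c, s in loci])

    shared_idx = np.sort(rng.choice(cfg.n_tf_peaks, cfg.n_tf_shared, replace=False))
    shared_set = set(shared_idx.tolist())
    tf_b = PeakSet("tf_b", [tf_a[i] for i in shared_idx])
    specific_idx = [i for i in range(cfg.n_tf_peaks) if i not in shared_set]

    n_spec = len(specific_idx)
    n_prom = round(cfg.frac_specific_promoter * n_spec)
    n_enh = round(cfg.frac_specific_enhancer * n_spec)
    perm = rng.permutation(n_spec)
    category = {}
    for rank, pos in enumerate(perm):
        idx = specific_idx[pos]
        if rank < n_prom:
            category[idx] = "promoter"
        elif rank < n_prom + n_enh:
            category[idx] = "enhancer"
        else:
            category[idx] = "intergenic"

    genes_rows = []
    enh_ivs = []
    gid = 0
    for idx in specific_idx:
        iv = tf_a[idx]
        if category[idx] == "promoter":
            gid += 1
            genes_rows.append(
                {"gene_id": f"g{gid:05d}", "chrom": iv.chrom,
                 "tss": iv.midpoint, "strand": "+" if rng.random() < 0.5 else "-"}
            )
        elif category[idx] == "enhancer":
            enh_ivs.append(GenomicInterval(iv.chrom, iv.start - 100, iv.end + 100))

    # decoys far from every peak slot (slots sit at margin + i*spacing)
    decoy_slots = _place_loci(
        rng, cfg.binding_genome, cfg.n_decoy_genes + cfg.n_decoy_enhancers,
        width=300, spacing=spacing, margin=4_000,
    )
    for c, s in decoy_slots[: cfg.n_decoy_genes]:
        gid += 1
        genes_rows.append(
            {"gene_id": f"g{gid:05d}", "chrom": c, "tss": s,
             "strand": "+" if rng.random() < 0.5 else "-"}
        )
    for c, s in decoy_slots[cfg.n_decoy_genes :]:
        enh_ivs.append(GenomicInterval(c, s, s + 300))
    genes = pd.DataFrame(genes_rows).sort_values("gene_id").reset_index(drop=True)
    enhancers = PeakSet("enhancers", enh_ivs).sorted()

    # genome sequence with motif embedding under bound (A) peaks
    seqs = {
        chrom: rng.integers(0, 4, size=length).astype(np.int8)
        for chrom, length in cfg.binding_genome.items()
    }
    motif_idx = np.array([BASES.index(b) for b in _MOTIF_CONSENSUS], dtype=np.int8)
    embedded = rng.random(cfg.n_tf_peaks) < cfg.motif_embed_rate
    for i, iv in enumerate(tf_a):
        if embedded[i]:
            pos = iv.midpoint - len(motif_idx) // 2
            seqs[iv.chrom][pos : pos + len(motif_idx)] = motif_idx
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    fasta = {
        chrom: base_arr[arr.astype(np.intp)].tobytes().decode()
        for chrom, arr in seqs.items()
    }

    # background windows: offset mid-way between slots, never embedded
    bg_slots = _place_loci(
        rng, cfg.binding_genome, cfg.n_background_seqs, width=width,
        spacing=spacing, margin=2_500,
    )
    background = PeakSet(
        "background", [GenomicInterval(c, s, s + width) for c, s in bg_slots]
    )

    truth = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in tf_a],
            "start": [iv.start for iv in tf_a],
            "end": [iv.end for iv in tf_a],
            "shared_with_b": [i in shared_set for i in range(cfg.n_tf_peaks)],
            "category": [category.get(i, "shared") for i in range(cfg.n_tf_peaks)],
            "motif_embedded": embedded,
        }
    )
    return BindingSim(genes, enhancers, tf_a, tf_b, fasta, default_pwm(),
                      background, truth)


# ---------------------------------------------------------------------------
# 3. expression
# ---------------------------------------------------------------------------

#: default cluster-size proportions (realistic relative DEG cluster sizes)
_CLUSTER_SIZES = {"C1": 961, "C2": 663, "C3": 472, "C4": 1101, "C5": 1210}


@dataclass
class ExpressionSim:
    profiles: pd.DataFrame  # gene_id + CONDITION_ORDER columns (means)
    de_table: pd.DataFrame  # gene_id, log2fc, q_value
    truth: pd.DataFrame  # gene_id, true_cluster, de_status


def simulate_expression(cfg: SimConfig) -> ExpressionSim:
    """WT/KO x day expression profiles from the five canonical templates.

    Per-gene means are a template scaled by a lognormal gene-level size
    factor; per-condition values are means of ``expr_replicates``
    negative-binomial draws at dispersion ``expr_dispersion``. The DE table
    plants n_de_up / n_de_down genes beyond the specificity thresholds
    (q < 0.05, |log2FC| > 1) and keeps every other gene strictly inside them.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_EXPRESSION)
    mix = cfg.cluster_mix or {
        k: v / sum(_CLUSTER_SIZES.values()) for k, v in _CLUSTER_SIZES.items()
    }
    names = list(mix)
    n = cfg.n_genes
    counts = [int(mix[c] * n) for c in names]
    for i in range(n - sum(counts)):
        counts[i % len(counts)] += 1
    labels = np.repeat(names, counts)
    rng.shuffle(labels)

    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    size = rng.lognormal(0.0, 0.3, size=n)
    templates = np.vstack([EXPRESSION_TEMPLATES[c] for c in labels])
    means = templates * size[:, None]
    reps = _nb_sample(
        rng,
        np.repeat(means[None, :, :], cfg.expr_replicates, axis=0),
        cfg.expr_dispersion,
    )
    profile_vals = reps.mean(axis=0)
    profiles = pd.DataFrame(profile_vals, columns=CONDITION_ORDER)
    profiles.insert(0, "gene_id", gene_ids)

    # DE table: planted up/down beyond thresholds, nulls strictly inside
    status = np.array(["null"] * n, dtype=object)
    de_idx = rng.choice(n, cfg.n_de_up + cfg.n_de_down, replace=False)
    status[de_idx[: cfg.n_de_up]] = "up"
    status[de_idx[cfg.n_de_up :]] = "down"
    log2fc = rng.uniform(-0.9, 0.9, size=n)
    q = rng.uniform(0.05, 1.0, size=n)
    up = status == "up"
    down = status == "down"
    log2fc[up] = rng.uniform(1.2, 4.0, size=up.sum())
    log2fc[down] = -rng.uniform(1.2, 4.0, size=down.sum())
    q[up | down] = rng.uniform(0.0, 0.04, size=(up | down).sum())
    de_table = pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "q_value": q})

    truth = pd.DataFrame(
        {"gene_id": gene_ids, "true_cluster": labels, "de_status": status}
    )
    return ExpressionSim(profiles, de_table, truth)


# ---------------------------------------------------------------------------
# 4. loops & contact matrices
# ---------------------------------------------------------------------------


@dataclass
class LoopSim:
    loops: list[LoopRecord]
    matrix_a: ContactMatrix
    matrix_b: ContactMatrix
    genes: pd.DataFrame  # promoters for annotation of anchors
    enhancers: PeakSet
    tf_peaks: PeakSet
    design: dict[str, str]  # sample -> condition
    size_factors_true: dict[str, float]
    truth: pd.DataFrame
    compartment_signs_a: np.ndarray
    compartment_signs_b: np.ndarray


def _anchor(chrom: str, bin_idx: int, resolution: int, width: int = 2_000) -> GenomicInterval:
    center = bin_idx * resolution + resolution // 2
    return GenomicInterval(chrom, center - width // 2, center + width // 2)


def simulate_loops_and_matrix(cfg: SimConfig) -> LoopSim:
    """Loop tables with replicate counts plus a condition pair of matrices.

    Loop counts are negative binomial around a lognormal baseline with the
    planted per-loop log2 fold-change (a ``frac_loops_down`` fraction
    decreased, a smaller ``frac_loops_up`` increased, the rest null) and
    per-sample size factors drawn log-uniform in [0.7, 1.4]. The matrix
    chromosome carries power-law distance decay, alternating compartment
    blocks (condition B flips ``switch_frac`` of bins), and multiplicative
    enrichment at the pixels of the loops that fit on it (one bin used per
    anchor at most once); loops beyond the matrix capacity live on count-only
    chromosomes.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_LOOPS)
    res, n_bins = cfg.resolution, cfg.n_bins
    w_margin = 12
    min_sep = 24

    # -- anchor placement: matrix chromosome first, unique bins per anchor --
    usable = np.arange(w_margin, n_bins - w_margin)

    def chrom_pairs(max_pairs: int) -> list[tuple[int, int]]:
        """Valid unique-bin pixel pairs on one chromosome (greedy pairing)."""
        pool = list(rng.permutation(usable))
        out: list[tuple[int, int]] = []
        while len(pool) >= 2 and len(out) < max_pairs:
            i, j = int(pool.pop()), int(pool.pop())
            if abs(i - j) >= min_sep:
                out.append((min(i, j), max(i, j)))
            # pairs violating the separation are simply dropped
        return out

    matrix_pairs = chrom_pairs(cfg.n_loops)
    anchors: list[tuple[GenomicInterval, GenomicInterval, Optional[tuple[int, int]]]] = []
    for i, j in matrix_pairs:
        anchors.append((_anchor("chrM", i, res), _anchor("chrM", j, res), (i, j)))
    ci = 0
    while len(anchors) < cfg.n_loops:
        ci += 1
        chrom = f"chrL{ci}"
        for i, j in chrom_pairs(cfg.n_loops - len(anchors)):
            anchors.append((_anchor(chrom, i, res), _anchor(chrom, j, res), None))
    n_loops = len(anchors)

    # -- planted effects --
    n_down = round(cfg.frac_loops_down * n_loops)
    n_up = round(cfg.frac_loops_up * n_loops)
    lfc = np.zeros(n_loops)
    eff_idx = rng.choice(n_loops, n_down + n_up, replace=False)
    lfc[eff_idx[:n_down]] = rng.uniform(*sorted(cfg.loop_log2fc_down), size=n_down)
    lfc[eff_idx[n_down:]] = rng.uniform(*sorted(cfg.loop_log2fc_up), size=n_up)

    # -- counts --
    samples = [f"{c}_rep{k + 1}" for c in ("condA", "condB") for k in range(cfg.replicates)]
    design = {s: ("A" if s.startswith("condA") else "B") for s in samples}
    sf = rng.uniform(math.log(0.7), math.log(1.4), size=len(samples))
    sf = np.exp(sf)
    base = rng.lognormal(cfg.loop_mean_log, cfg.loop_mean_sigma, size=n_loops)
    mean_a = base
    mean_b = base * np.exp2(lfc)
    mu = np.where(
        np.array([design[s] == "B" for s in samples])[None, :],
        mean_b[:, None], mean_a[:, None],
    ) * sf[None, :]
    counts = _nb_sample(rng, mu, cfg.nb_dispersion)

    # -- confidence FDR --
    low_conf = rng.random(n_loops) < cfg.frac_low_confidence
    fdr = np.where(low_conf, rng.uniform(0.05, 0.5, n_loops),
                   rng.uniform(0.0, 0.05, n_loops))

    # -- anchor classes and TF binding --
    is_ep = rng.random(n_loops) < cfg.frac_ep
    tf_at_enh = is_ep & (rng.random(n_loops) < cfg.frac_tf_of_ep)
    genes_rows, enh_ivs, tf_ivs = [], [], []
    loops: list[LoopRecord] = []
    class_a_list, class_b_list = [], []
    gid = 0
    for li, (a, b, pix) in enumerate(anchors):
        cnts = {s: int(counts[li, si]) for si, s in enumerate(samples)}
        loops.append(LoopRecord(a, b, cnts, fdr=float(fdr[li])))
        if is_ep[li]:
            # promoter at anchor a, enhancer at anchor b
            gid += 1
            genes_rows.append(
                {"gene_id": f"lg{gid:05d}", "chrom": a.chrom,
                 "tss": a.midpoint, "strand": "+"}
            )
            enh_ivs.append(GenomicInterval(b.chrom, b.start, b.end))
            class_a_list.append("promoter")
            class_b_list.append("enhancer")
            if tf_at_enh[li]:
                tf_ivs.append(GenomicInterval(b.chrom, b.midpoint - 150,
                                              b.midpoint + 150))
        else:
            class_a_list.append("other")
            class_b_list.append("other")
    genes = pd.DataFrame(genes_rows)
    enhancers = PeakSet("enhancers", enh_ivs)
    tf_peaks = PeakSet("tf", tf_ivs)

    # -- contact matrices (matrix chromosome only) --
    signs_a = np.ones(n_bins)
    block = cfg.compartment_block
    for start in range(0, n_bins, block):
        if (start // block) % 2 == 1:
            signs_a[start : start + block] = -1
    n_switch = round(cfg.switch_frac * n_bins)
    flip = rng.choice(n_bins, n_switch, replace=False)
    signs_b = signs_a.copy()
    signs_b[flip] *= -1

    def build_matrix(signs: np.ndarray, pixel_factor: dict[tuple[int, int], float]) -> ContactMatrix:
        d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
        base_mat = cfg.matrix_depth * (1.0 + d) ** (-cfg.decay_exponent)
        base_mat *= 1.0 + cfg.compartment_strength * np.outer(signs, signs)
        for (i, j), f in pixel_factor.items():
            base_mat[i, j] *= f
            base_mat[j, i] *= f
        upper = rng.poisson(np.triu(base_mat))
        counts_mat = upper + np.triu(upper, 1).T
        return ContactMatrix("chrM", res, counts_mat.astype(float),
                             np.ones(n_bins, dtype=bool))

    pf_a = {pix: cfg.loop_enrichment
            for (_, _, pix) in anchors if pix is not None}
    pf_b = {
        pix: cfg.loop_enrichment * float(np.exp2(lfc[li]))
        for li, (_, _, pix) in enumerate(anchors)
        if pix is not None
    }
    matrix_a = build_matrix(signs_a, pf_a)
    matrix_b = build_matrix(signs_b, pf_b)

    truth = pd.DataFrame(
        {
            "chrom": [a.chrom for a, _, _ in anchors],
            "bin_i": [p[0] if p else -1 for _, _, p in anchors],
            "bin_j": [p[1] if p else -1 for _, _, p in anchors],
            "true_log2fc": lfc,
            "is_ep": is_ep,
            "tf_bound": tf_at_enh,
            "low_confidence": low_conf,
            "base_mean": base,
        }
    )
    return LoopSim(
        loops, matrix_a, matrix_b, genes, enhancers, tf_peaks, design,
        dict(zip(samples, sf)), truth, signs_a, signs_b,
    )
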