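"""End-to-end orchestration of the four analysis stages from one config.

``run_pipeline`` executes, in dependency order: synthetic-input generation
(or consumption of caller files via the per-stage APIs), accessibility-
dynamics classification for both transition directions, condition-specific
TF-binding and motif enrichment, expression specificity and clustering, and
the 3D-genome stage (KR balancing, compartments, differential EP loops, APA,
SCC). Stage outputs land in a run directory together with a machine-readable
``summary.json``; a rerun with the same config is bit-identical.

Every default threshold matches the field-standard criteria: DE specificity
q < 0.05 and fold-change > 2; loop confidence FDR < 0.05; differential loops
at p < 0.05 and |log2FC| > 1; compartments at the matrix's bin resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import binding, contacts, dynamics, expression, io, loops as loops_mod
from .simulate import SimConfig, simulate_annotation_and_binding, \
    simulate_expression, simulate_loops_and_matrix, simulate_timecourse_peaks

PathLike = Union[str, Path]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """All stage parameters plus the synthetic-input configuration."""

    seed: int = 0
    out_dir: str = "chromdyn_run"
    promoter_window: int = 2_000
    max_dist: int = 100_000
    frac_of_max: float = 0.8
    q_max: float = 0.05
    fc_min: float = 2.0
    k_clusters: int = 5
    fdr_max: float = 0.05
    p_max: float = 0.05
    lfc_min: float = 1.0
    min_total: int = 5
    apa_w: int = 10
    apa_norm: str = "oe"
    tf_anchor_rule: str = "either"
    scc_h: int = 1
    scc_max_dist: int = 5_000_000
    timing_bins: tuple = ((1, 2), (3, 4, 5))
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed
        self.timing_bins = tuple(tuple(b) for b in self.timing_bins)

    def validate(self) -> None:
        try:
            self.sim.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.tf_anchor_rule not in ("either", "both", "enhancer_only", "promoter_only"):
            raise ConfigError(f"unknown tf_anchor_rule {self.tf_anchor_rule!r}")
        if not 0 < self.frac_of_max <= 1:
            raise ConfigError("frac_of_max must be in (0, 1]")

    def to_yaml(self, path: PathLike) -> None:
        d = asdict(self)
        d["timing_bins"] = [list(b) for b in self.timing_bins]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _tss_grid(genome: dict[str, int], spacing: int = 5_000) -> pd.DataFrame:
    """Deterministic TSS grid over a toy genome (demo peak->gene mapping)."""
    rows = []
    gid = 0
    for chrom, length in sorted(genome.items()):
        pos = spacing // 2
        while pos < length:
            gid += 1
            rows.append({"gene_id": f"t{gid:05d}", "chrom": chrom,
                         "tss": pos, "strand": "+"})
            pos += spacing
    return pd.DataFrame(rows)


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs; returns the summary dict.

    Inputs are generated from cfg.sim, written under <out_dir>/inputs, read
    back through the io layer (so the emitted files are what is analysed),
    and each stage's headline statistics are collected into summary.json.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    inputs = out / "inputs"
    results = out / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # ---- stage 0: synthetic inputs ----
    tc_fwd = simulate_timecourse_peaks(cfg.sim, "fwd")
    tc_rev = simulate_timecourse_peaks(cfg.sim, "rev")
    bind = simulate_annotation_and_binding(cfg.sim)
    expr = simulate_expression(cfg.sim)
    lsim = simulate_loops_and_matrix(cfg.sim)

    for direction, tc in (("sl2il", tc_fwd), ("2il2sl", tc_rev)):
        for ps in tc.peak_sets:
            io.write_bed(ps, inputs / f"atac_{direction}_{ps.name}.bed")
        tc.truth.to_csv(inputs / f"truth_{direction}.tsv", sep="\t", index=False)
    io.write_tss_table(bind.genes, inputs / "genes.tsv")
    io.write_bed(bind.enhancers, inputs / "enhancers.bed")
    io.write_bed(bind.tf_a, inputs / "tf_2il.bed")
    io.write_bed(bind.tf_b, inputs / "tf_sl.bed")
    io.write_bed(bind.background, inputs / "background.bed")
    io.write_fasta(bind.fasta, inputs / "genome.fa")
    io.write_pwms([bind.pwm], inputs / "motifs.txt")
    expr.profiles.to_csv(inputs / "profiles.tsv", sep="\t", index=False)
    expr.de_table.to_csv(inputs / "de.tsv", sep="\t", index=False)
    io.write_bedpe(loops_mod.loops_to_frame(lsim.loops), inputs / "loops.bedpe")
    lsim.matrix_a.to_triplets(inputs / "matrix_condA.txt")
    lsim.matrix_b.to_triplets(inputs / "matrix_condB.txt")

    # ---- stage 1: accessibility dynamics ----
    regions = {}
    consensus = {}
    for direction in ("sl2il", "2il2sl"):
        sets = [
            io.read_bed(inputs / f"atac_{direction}_d{3 * t}.bed")
            for t in range(cfg.sim.n_timepoints)
        ]
        cons = dynamics.build_consensus(sets)
        labels, counts = dynamics.classify_dynamics(cons)
        consensus[direction] = (cons, labels)
        pd.DataFrame(
            {
                "chrom": [c.interval.chrom for c in cons],
                "start": [c.interval.start for c in cons],
                "end": [c.interval.end for c in cons],
                "open_vector": ["".join("1" if b else "0" for b in c.open_state)
                                for c in cons],
                "label": [str(l) for l in labels],
            }
        ).to_csv(results / f"dynamics_{direction}.tsv", sep="\t", index=False)
        summary[f"dynamics_{direction}_class_counts"] = dict(sorted(counts.items()))
    region_map = dynamics.define_regions(
        consensus["sl2il"][0], consensus["sl2il"][1],
        consensus["2il2sl"][0], consensus["2il2sl"][1],
    )
    summary["region_counts"] = {f"region{r}": len(a) for r, a in region_map.items()}
    summary["region1_vs_region4"] = dynamics.region_overlap_stats(
        region_map[1], region_map[4]
    )
    summary["region2_vs_region3"] = dynamics.region_overlap_stats(
        region_map[2], region_map[3]
    )

    # switch-timing over a deterministic gene grid on the time-course genome
    tc_genes = _tss_grid(cfg.sim.genome)
    for pair, a, b in (("region1_4", 1, 4), ("region2_3", 2, 3)):
        peaks = region_map[a].peak_set()
        labels = list(region_map[a].labels)
        offset = len(peaks)
        peaks.intervals.extend(iv for iv in region_map[b].peak_set())
        labels.extend(region_map[b].labels)
        ann = binding.AnnotationSet.from_genes(
            tc_genes, binding.PeakSet("none"), cfg.promoter_window
        )
        mapping, _ = binding.assign_peaks_to_genes(
            peaks, tc_genes, ann, cfg.max_dist
        )
        timing = dynamics.switch_timing_table(
            labels, {i: [g] for i, g in mapping.items()}, cfg.timing_bins
        )
        timing.to_csv(results / f"timing_{pair}.tsv", sep="\t", index=False)
        summary[f"timing_{pair}"] = timing.to_dict(orient="records")

    # ---- stage 2: TF binding and motifs ----
    tf_a = io.read_bed(inputs / "tf_2il.bed")
    tf_b = io.read_bed(inputs / "tf_sl.bed")
    genes = io.read_tss_table(inputs / "genes.tsv")
    enhancers = io.read_bed(inputs / "enhancers.bed")
    fasta = io.read_fasta(inputs / "genome.fa")
    pwm = io.read_pwms(inputs / "motifs.txt")[0]
    split = binding.condition_specific_peaks(tf_a, tf_b)
    summary["tf_peaks"] = {
        "n_2il": len(tf_a), "n_sl": len(tf_b),
        "n_2il_specific": len(split["a_specific"]),
        "n_sl_specific": len(split["b_specific"]),
        "n_shared": len(split["shared"]),
    }
    ann = binding.AnnotationSet.from_genes(genes, enhancers, cfg.promoter_window)
    summary["tf_specific_distribution"] = binding.genomic_distribution(
        split["a_specific"], ann
    )
    mapping, target_genes = binding.assign_peaks_to_genes(
        split["a_specific"], genes, ann, cfg.max_dist
    )
    summary["n_tf_target_genes"] = len(target_genes)
    target_seqs = io.extract_sequences(fasta, split["a_specific"])
    bg_seqs = io.extract_sequences(fasta, io.read_bed(inputs / "background.bed"))
    enr = binding.motif_enrichment(target_seqs, bg_seqs, pwm, cfg.frac_of_max)
    summary["motif_enrichment"] = enr

    # ---- stage 3: expression ----
    de = pd.read_csv(inputs / "de.tsv", sep="\t")
    spec = expression.define_specific_genes(de, cfg.q_max, cfg.fc_min)
    summary["n_2i_specific_genes"] = len(spec["two_i_specific"])
    summary["n_serum_specific_genes"] = len(spec["serum_specific"])
    profiles = pd.read_csv(inputs / "profiles.tsv", sep="\t")
    clust = expression.cluster_time_profiles(profiles, cfg.k_clusters, cfg.seed)
    clust.assignments.to_csv(results / "clusters.tsv", sep="\t", index=False)
    sizes = clust.assignments["cluster"].value_counts().sort_index()
    summary["cluster_sizes"] = sizes.to_dict()
    c5 = set(clust.assignments.loc[clust.assignments["cluster"] == "C5", "gene_id"])
    if c5:
        summary["c5_targeted_by_tf"] = expression.fraction_in_set(c5, target_genes)

    # ---- stage 4: loops and matrices ----
    loop_df = io.read_bedpe(inputs / "loops.bedpe")
    all_loops = loops_mod.loops_from_frame(loop_df)
    confident = loops_mod.filter_confident(all_loops, cfg.fdr_max)
    annotated, ep_idx, tf_ep_idx = loops_mod.annotate_loops(
        confident, binding.AnnotationSet.from_genes(
            lsim.genes, lsim.enhancers, cfg.promoter_window
        ),
        lsim.tf_peaks, cfg.tf_anchor_rule,
    )
    design = loops_mod.design_from_samples(loops_mod.sample_columns(loop_df))
    results_all, factors = loops_mod.diff_loop_test(
        annotated, design, cfg.p_max, cfg.lfc_min, cfg.min_total
    )
    loops_mod.results_to_frame(annotated, results_all).to_csv(
        results / "diff_loops.tsv", sep="\t", index=False
    )
    tf_ep_loops = [annotated[i] for i in tf_ep_idx]
    tf_ep_results = [results_all[i] for i in tf_ep_idx]
    summary["loops"] = {
        "n_total": len(all_loops),
        "n_confident": len(confident),
        "n_ep": len(ep_idx),
        "n_tf_ep": len(tf_ep_idx),
    }
    summary["diff_tf_ep"] = loops_mod.summarize_diff_ep(
        tf_ep_loops, tf_ep_results, design, factors
    )

    mat_a = contacts.ContactMatrix.from_triplets(inputs / "matrix_condA.txt")
    mat_b = contacts.ContactMatrix.from_triplets(inputs / "matrix_condB.txt")
    bal_a, _, info_a = contacts.kr_balance(mat_a)
    bal_b, _, info_b = contacts.kr_balance(mat_b)
    summary["kr_balance"] = {"condA": info_a, "condB": info_b}
    track = lsim.compartment_signs_a  # activity proxy for sign orientation
    comp_a = contacts.compartment_eigenvector(mat_a, track)
    comp_b = contacts.compartment_eigenvector(mat_b, track)
    summary["compartment_switch"] = contacts.compartment_switch(comp_a, comp_b)
    matrix_loops = [
        lp for lp, on in zip(all_loops, lsim.truth["bin_i"] >= 0) if on
    ]
    apa_a = contacts.apa(mat_a, matrix_loops, cfg.apa_w, cfg.apa_norm)
    apa_b = contacts.apa(mat_b, matrix_loops, cfg.apa_w, cfg.apa_norm)
    summary["apa"] = {
        "condA": {"score": apa_a.apa_score, "n_loops": apa_a.n_loops_used},
        "condB": {"score": apa_b.apa_score, "n_loops": apa_b.n_loops_used},
    }
    summary["scc_condA_vs_condB"] = contacts.scc(
        mat_a, mat_b, cfg.scc_h, cfg.scc_max_dist
    )

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
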