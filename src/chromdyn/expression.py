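"""Condition-specific gene definition and five-pattern knockout clustering.

Stage 3. A differential-expression table (ground-state vs serum, consumed
from an upstream DESeq2-style fit) defines 2i-specific (up) and
serum-specific (down) genes at q < 0.05 and fold-change > 2. Wild-type /
knockout time-course profiles over (WT, KO) x (day 0, 3, 6) are clustered
into five canonical response patterns:

  C1  unchanged throughout;
  C2  lower in the knockout at the serum baseline (day 0) only;
  C3  aberrantly high in the knockout during the transition;
  C4  normally upregulated in both genotypes;
  C5  upregulated in wild type, failing to rise in the knockout.

Profiles are log2(x+1)-transformed, centered per gene and scaled by a
variance-floored standard deviation so that flat (C1) genes stay near the
origin instead of becoming amplified noise, then partitioned by k-means and
mapped to the semantic labels by nearest canonical pattern (one-to-one,
Hungarian assignment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from ._util import round_half_up

#: fixed condition order for every profile table
CONDITION_ORDER = ["WT_d0", "WT_d3", "WT_d6", "KO_d0", "KO_d3", "KO_d6"]

#: canonical mean-expression templates per pattern (arbitrary count units)
EXPRESSION_TEMPLATES: dict[str, np.ndarray] = {
    "C1": np.array([50.0, 50.0, 50.0, 50.0, 50.0, 50.0]),
    "C2": np.array([50.0, 50.0, 50.0, 25.0, 50.0, 50.0]),
    "C3": np.array([50.0, 50.0, 50.0, 50.0, 150.0, 150.0]),
    "C4": np.array([20.0, 60.0, 120.0, 20.0, 60.0, 120.0]),
    "C5": np.array([20.0, 60.0, 120.0, 20.0, 22.0, 24.0]),
}

#: floor on the per-gene standard deviation (log2 units) used for scaling
Z_FLOOR = 0.5


class DataError(ValueError):
    """Raised on malformed analysis inputs."""


def define_specific_genes(
    de: pd.DataFrame, q_max: float = 0.05, fc_min: float = 2.0
) -> dict[str, object]:
    """Split a DE table into 2i-specific (up) and serum-specific (down) genes.

    ``de`` needs columns gene_id, log2fc (ground-state vs serum) and q_value.
    2i-specific: q < q_max and log2fc > log2(fc_min); serum-specific:
    q < q_max and log2fc < -log2(fc_min). Non-finite log2fc rows are skipped
    and counted.
    """
    if fc_min <= 1:
        raise DataError(f"fc_min must be > 1, got {fc_min}")
    required = {"gene_id", "log2fc", "q_value"}
    if not required <= set(de.columns):
        raise DataError(f"DE table missing columns {sorted(required - set(de.columns))}")
    finite = np.isfinite(de["log2fc"].to_numpy(dtype=float))
    n_skipped = int((~finite).sum())
    d = de.loc[finite]
    lfc_cut = math.log2(fc_min)
    sig = d["q_value"] < q_max
    up = set(d.loc[sig & (d["log2fc"] > lfc_cut), "gene_id"].astype(str))
    down = set(d.loc[sig & (d["log2fc"] < -lfc_cut), "gene_id"].astype(str))
    return {"two_i_specific": up, "serum_specific": down, "n_skipped": n_skipped}


def _floored_z(profiles: np.ndarray, floor: float = Z_FLOOR) -> np.ndarray:
    """log2(x+1), center per gene, scale by max(sd, floor)."""
    logged = np.log2(profiles + 1.0)
    centered = logged - logged.mean(axis=1, keepdims=True)
    sd = np.maximum(logged.std(axis=1), floor)
    return centered / sd[:, None]


def _template_patterns(floor: float = Z_FLOOR) -> dict[str, np.ndarray]:
    names = list(EXPRESSION_TEMPLATES)
    mat = np.vstack([EXPRESSION_TEMPLATES[n] for n in names])
    z = _floored_z(mat, floor)
    return dict(zip(names, z))


@dataclass
class ClusterResult:
    assignments: pd.DataFrame  # gene_id, cluster
    centroids: pd.DataFrame  # cluster x condition, in scaled log space
    label_map: dict[int, str]


def cluster_time_profiles(
    profiles: pd.DataFrame, k: int = 5, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """k-means over scaled log profiles, mapped to the C1-C5 taxonomy.

    ``profiles`` must carry gene_id plus the six CONDITION_ORDER columns.
    With k=5 the raw clusters are relabeled C1-C5 by minimal Euclidean
    distance between each centroid and the canonical template patterns
    (a bijection via the Hungarian algorithm); for other k the labels are
    K1..Kk in centroid order.
    """
    missing = [c for c in ["gene_id", *CONDITION_ORDER] if c not in profiles.columns]
    if missing:
        raise DataError(f"profile table missing columns {missing}")
    X_raw = profiles[CONDITION_ORDER].to_numpy(dtype=float)
    if (X_raw < 0).any() or not np.isfinite(X_raw).all():
        raise DataError("profiles must be finite and non-negative")
    if len(profiles) < k:
        raise DataError(f"need >= {k} genes, got {len(profiles)}")
    X = _floored_z(X_raw)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(X)

    if k == len(EXPRESSION_TEMPLATES):
        patterns = _template_patterns()
        names = list(patterns)
        cost = np.array(
            [
                [np.linalg.norm(km.cluster_centers_[c] - patterns[n]) for n in names]
                for c in range(k)
            ]
        )
        rows, cols = linear_sum_assignment(cost)
        label_map = {int(r): names[c] for r, c in zip(rows, cols)}
    else:
        label_map = {c: f"K{c + 1}" for c in range(k)}

    assignments = pd.DataFrame(
        {
            "gene_id": profiles["gene_id"].astype(str).to_numpy(),
            "cluster": [label_map[c] for c in raw_labels],
        }
    )
    centroids = pd.DataFrame(
        km.cluster_centers_,
        columns=CONDITION_ORDER,
        index=[label_map[c] for c in range(k)],
    ).sort_index()
    return ClusterResult(assignments, centroids, label_map)


def fraction_in_set(cluster_genes: set[str], reference: set[str]) -> dict[str, float]:
    """Count and percentage of a cluster's genes found in a reference set."""
    if not cluster_genes:
        raise ZeroDivisionError("empty cluster; percent undefined")
    count = len(cluster_genes & reference)
    raw = 100.0 * count / len(cluster_genes)
    return {
        "count": count,
        "n_cluster": len(cluster_genes),
        "percent": round_half_up(raw, 1),
        "percent_raw": raw,
    }
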