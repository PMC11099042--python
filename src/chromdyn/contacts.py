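"""Binned intra-chromosomal contact-matrix analytics.

Stage 4a: Knight-Ruiz matrix balancing, A/B compartment eigenvectors
(observed/expected -> Pearson correlation -> leading eigenvector, at 100-kb
resolution by default), compartment-switch statistics, aggregate peak
analysis (APA) around loop pixels, and the HiCRep-style stratum-adjusted
correlation coefficient (SCC) for reproducibility.

Matrices travel as coordinate-triplet text (bin_i, bin_j, count) under a
small header naming the chromosome, resolution and bin count; in memory they
are dense symmetric numpy arrays with a per-bin validity mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import uniform_filter

PathLike = Union[str, Path]

DEFAULT_COMPARTMENT_RESOLUTION = 100_000


class MatrixError(ValueError):
    """Raised for degenerate or inconsistent contact matrices."""


@dataclass
class ContactMatrix:
    """Symmetric non-negative binned contact matrix for one chromosome."""

    chrom: str
    resolution: int
    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # True = valid bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape != (n, n):
            raise MatrixError("counts must be square")
        if not np.allclose(self.counts, self.counts.T, rtol=1e-8, atol=1e-8):
            raise MatrixError("counts must be symmetric")
        if (self.counts < 0).any():
            raise MatrixError("counts must be non-negative")
        if self.mask is None:
            self.mask = self.counts.sum(axis=0) > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise MatrixError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def scaled(self, factor: float) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.resolution, self.counts * factor,
                             self.mask.copy())

    def to_triplets(self, path: PathLike) -> None:
        """Write the upper triangle (including diagonal) as triplet text."""
        with open(path, "w") as fh:
            fh.write(f"#chrom={self.chrom}\n")
            fh.write(f"#resolution={self.resolution}\n")
            fh.write(f"#n_bins={self.n_bins}\n")
            iu = np.triu_indices(self.n_bins)
            for i, j in zip(*iu):
                v = self.counts[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:g}\n")

    @classmethod
    def from_triplets(cls, path: PathLike) -> "ContactMatrix":
        meta: dict[str, str] = {}
        rows: list[tuple[int, int, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise MatrixError(f"{path}:{lineno}: expected 3 columns")
                rows.append((int(parts[0]), int(parts[1]), float(parts[2])))
        for key in ("chrom", "resolution", "n_bins"):
            if key not in meta:
                raise MatrixError(f"{path}: missing header field #{key}=")
        n = int(meta["n_bins"])
        counts = np.zeros((n, n))
        for i, j, v in rows:
            counts[i, j] = v
            counts[j, i] = v
        return cls(meta["chrom"], int(meta["resolution"]), counts)


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------


def _kr_newton(
    A: np.ndarray, tol: float, max_outer: int = 100, delta: float = 0.1,
    upper: float = 3.0,
) -> tuple[np.ndarray, bool]:
    """Knight-Ruiz inner-outer Newton/CG iteration on a positive matrix.

    Finds x > 0 with x * (A x) = 1 (unit row sums after symmetric scaling).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rold = rho_km1
    outer = 0
    while rout > rt and outer < max_outer:
        outer += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_inner = rho_km1
        rho_km2 = rho_inner
        Z = p = w = None
        while rho_inner > innertol and k < 200:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_inner = float(rk @ Z)
                if rho_inner <= innertol:
                    break
            else:
                beta = rho_inner / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0 or not np.isfinite(denom):
                return x, False
            alpha = rho_inner / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = float(((delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            if ynew.max() >= upper:
                ind = ynew > upper
                gamma = float(((upper - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_inner
            Z = rk / v
            rho_inner = float(rk @ Z)
        x = x * y
        if not np.isfinite(x).all() or x.min() <= 0:
            return x, False
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        eta = max(min(g * rat, etamax), rt / max(rout, rt))
    return x, rout <= rt


def _damped_scaling(
    A: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, bool, int]:
    """Fallback: damped iterative proportional (Sinkhorn-style) scaling."""
    n = A.shape[0]
    x = np.ones(n)
    for it in range(1, max_iter + 1):
        s = x * (A @ x)
        if np.max(np.abs(s - 1.0)) < tol:
            return x, True, it
        x = np.sqrt(x / (A @ x))
    return x, False, max_iter


def kr_balance(
    m: ContactMatrix, tol: float = 1e-8, max_iter: int = 3000
) -> tuple[ContactMatrix, np.ndarray, dict]:
    """Knight-Ruiz balance so every unmasked row sums to 1.

    Returns (balanced matrix, bias vector with NaN at masked bins, info).
    Masked bins are removed from the system and stay zero in the output.
    Non-convergence of the Newton iteration falls back to damped iterative
    proportional scaling (reported in ``info['method']``).
    """
    idx = np.flatnonzero(m.mask)
    if idx.size == 0:
        raise MatrixError("all bins masked; nothing to balance")
    A = m.counts[np.ix_(idx, idx)]
    if (A.sum(axis=0) == 0).any():
        # a zero row within the unmasked system cannot be balanced
        raise MatrixError("unmasked bin with zero contacts; extend the mask")
    # pre-scale to mean row sum 1: the Newton iteration's cone bounds assume
    # biases of order one; the bias is rescaled back afterwards
    scale = A.sum(axis=1).mean()
    x, converged = _kr_newton(A / scale, tol)
    x = x / math.sqrt(scale)
    method = "kr"
    iters = None
    if not converged:
        x, converged, iters = _damped_scaling(A, tol, max_iter)
        method = "ipf"
    bias = np.full(m.n_bins, np.nan)
    bias[idx] = x
    balanced = np.zeros_like(m.counts)
    balanced[np.ix_(idx, idx)] = A * np.outer(x, x)
    out = ContactMatrix(m.chrom, m.resolution, balanced, m.mask.copy())
    row_sums = balanced[np.ix_(idx, idx)].sum(axis=1)
    info = {
        "method": method,
        "converged": bool(converged),
        "iterations": iters,
        "max_rel_rowsum_dev": float(np.max(np.abs(row_sums - 1.0))),
    }
    return out, bias, info


# ---------------------------------------------------------------------------
# Expected-by-distance and O/E
# ---------------------------------------------------------------------------


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean contact per diagonal over unmasked bin pairs."""
    n = m.n_bins
    exp = np.zeros(n)
    valid = m.mask
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = valid[i] & valid[j]
        if ok.any():
            exp[d] = m.counts[i[ok], j[ok]].mean()
    return exp


def oe_matrix(m: ContactMatrix) -> np.ndarray:
    """Observed/expected matrix; zero rows/cols at masked bins."""
    exp = expected_by_distance(m)
    n = m.n_bins
    i, j = np.indices((n, n))
    d = np.abs(i - j)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp[d] > 0, m.counts / exp[d], 0.0)
    oe[~m.mask, :] = 0.0
    oe[:, ~m.mask] = 0.0
    return oe


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------


@dataclass
class CompartmentTrack:
    chrom: str
    resolution: int
    eigenvector: np.ndarray  # NaN at masked bins
    labels: np.ndarray  # 'A' / 'B' / '.' per bin

    @property
    def n_bins(self) -> int:
        return self.eigenvector.size


def _power_iteration(
    C: np.ndarray, tol: float = 1e-8, max_iter: int = 10_000
) -> np.ndarray:
    n = C.shape[0]
    v = np.ones(n) + 1e-3 * np.arange(n)  # deterministic start
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = C @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise MatrixError("power iteration hit the zero vector")
        w /= norm
        if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
            return w
        v = w
    return v


def compartment_eigenvector(
    m: ContactMatrix,
    orientation_track: Optional[np.ndarray] = None,
    min_bins: int = 20,
) -> CompartmentTrack:
    """A/B compartment call: O/E -> Pearson correlation -> leading eigenvector.

    The eigenvector's overall sign is arbitrary; when ``orientation_track``
    (e.g. gene density or accessibility coverage per bin) is supplied and
    correlates negatively with the eigenvector, the sign is flipped so that
    positive values (A) mark the active compartment. Labels: A for positive,
    B for negative, '.' for masked bins.
    """
    idx = np.flatnonzero(m.mask)
    if idx.size < min_bins:
        raise MatrixError(f"need >= {min_bins} unmasked bins, got {idx.size}")
    oe = oe_matrix(m)[np.ix_(idx, idx)]
    sd = oe.std(axis=0)
    if (sd == 0).any():
        keep = sd > 0
        idx = idx[keep]
        if idx.size < min_bins:
            raise MatrixError("too many constant O/E bins")
        oe = oe[np.ix_(keep, keep)]
    C = np.corrcoef(oe)
    if not np.isfinite(C).all() or np.allclose(C, C.flat[0]):
        raise MatrixError("degenerate correlation matrix; compartments undefined")
    ev = _power_iteration(C)
    full = np.full(m.n_bins, np.nan)
    full[idx] = ev
    if orientation_track is not None:
        track = np.asarray(orientation_track, dtype=float)
        if track.shape != (m.n_bins,):
            raise MatrixError("orientation track length must equal n_bins")
        r = np.corrcoef(ev, track[idx])[0, 1]
        if np.isfinite(r) and r < 0:
            full = -full
    labels = np.full(m.n_bins, ".", dtype=object)
    labels[np.nan_to_num(full) > 0] = "A"
    labels[np.nan_to_num(full) < 0] = "B"
    labels[~np.isfinite(full)] = "."
    return CompartmentTrack(m.chrom, m.resolution, full, labels)


def compartment_switch(a: CompartmentTrack, b: CompartmentTrack) -> dict[str, float]:
    """Percentage of jointly valid bins switching A->B and B->A."""
    if (a.n_bins, a.resolution, a.chrom) != (b.n_bins, b.resolution, b.chrom):
        raise MatrixError("compartment tracks are not comparable")
    valid = np.isfinite(a.eigenvector) & np.isfinite(b.eigenvector)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise MatrixError("no jointly valid bins")
    la, lb = a.labels[valid], b.labels[valid]
    a_to_b = int(((la == "A") & (lb == "B")).sum())
    b_to_a = int(((la == "B") & (lb == "A")).sum())
    return {
        "pct_A_to_B": 100.0 * a_to_b / n_valid,
        "pct_B_to_A": 100.0 * b_to_a / n_valid,
        "n_valid": n_valid,
    }


# ---------------------------------------------------------------------------
# APA
# ---------------------------------------------------------------------------


@dataclass
class APAResult:
    aggregate: np.ndarray  # (2w+1) x (2w+1)
    apa_score: float
    n_loops_used: int
    n_loops_skipped: int


def _loop_bins(loop, resolution: int) -> tuple[int, int]:
    a, b = (loop if isinstance(loop, tuple) else (loop.anchor_a, loop.anchor_b))
    return a.midpoint // resolution, b.midpoint // resolution


def apa(
    m: ContactMatrix,
    loops: Sequence,
    w: int = 10,
    norm: str = "oe",
) -> APAResult:
    """Aggregate peak analysis around loop pixels.

    Per usable loop the (2w+1)^2 submatrix centered on the anchor-bin pixel is
    extracted (from the O/E matrix when ``norm='oe'``, raw counts otherwise)
    and element-wise averaged. Loops whose pixel sits closer than 2w+2 bins to
    the diagonal or within w bins of the matrix edge are skipped and counted.
    apa_score = center pixel over the mean of the (w//2+1)-sized lower-left
    corner block (the P2LL convention: the corner nearest the diagonal).
    """
    if norm not in ("observed", "oe"):
        raise ValueError(f"unknown norm {norm!r}")
    X = oe_matrix(m) if norm == "oe" else m.counts
    n = m.n_bins
    size = 2 * w + 1
    agg = np.zeros((size, size))
    used = skipped = 0
    for loop in loops:
        bi, bj = _loop_bins(loop, m.resolution)
        if bi > bj:
            bi, bj = bj, bi
        if (
            bj - bi < 2 * w + 2
            or bi - w < 0
            or bj + w >= n
            or bi + w >= n
            or bj - w < 0
        ):
            skipped += 1
            continue
        agg += X[bi - w : bi + w + 1, bj - w : bj + w + 1]
        used += 1
    if used == 0:
        raise MatrixError("no usable loops for APA")
    agg /= used
    c = w // 2 + 1
    corner = agg[size - c :, :c]  # lower-left block
    corner_mean = corner.mean()
    score = float(agg[w, w] / corner_mean) if corner_mean > 0 else float("nan")
    return APAResult(agg, score, used, skipped)


# ---------------------------------------------------------------------------
# HiCRep-style SCC
# ---------------------------------------------------------------------------


def _mean_filter(X: np.ndarray, h: int) -> np.ndarray:
    """(2h+1)^2 mean filter averaging only in-bounds cells."""
    if h == 0:
        return X
    size = 2 * h + 1
    num = uniform_filter(X, size=size, mode="constant", cval=0.0)
    den = uniform_filter(np.ones_like(X), size=size, mode="constant", cval=0.0)
    return num / den


def scc(
    a: ContactMatrix,
    b: ContactMatrix,
    h: int = 1,
    max_dist: int = 5_000_000,
) -> float:
    """Stratum-adjusted correlation coefficient between two matrices.

    Both matrices are smoothed with a (2h+1)^2 mean filter; per distance
    stratum d (1 .. max_dist/resolution bins) the Pearson correlation of the
    two strata is weighted by stratum size times the product of the stratum
    standard deviations. Bins masked in either matrix are excluded.
    """
    if a.n_bins != b.n_bins or a.resolution != b.resolution:
        raise MatrixError("matrices must share shape and resolution")
    Xa = _mean_filter(a.counts, h)
    Xb = _mean_filter(b.counts, h)
    valid = a.mask & b.mask
    n = a.n_bins
    d_max = min(n - 1, max_dist // a.resolution)
    num = den = 0.0
    any_stratum = False
    for d in range(1, d_max + 1):
        i = np.arange(n - d)
        j = i + d
        ok = valid[i] & valid[j]
        if ok.sum() < 2:
            continue
        x, y = Xa[i[ok], j[ok]], Xb[i[ok], j[ok]]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        rho = float(np.corrcoef(x, y)[0, 1])
        weight = ok.sum() * sx * sy
        num += weight * rho
        den += weight
        any_stratum = True
    if not any_stratum:
        raise MatrixError("no stratum with >= 2 valid, varying pairs")
    return num / den
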