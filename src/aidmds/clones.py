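"""Clone-level processivity statistics.

A processive deaminase that scans a short stretch of exposed ssDNA
leaves correlated mutations on individual molecules.  Working from the
binary clone x C-site indicator matrix (h_i = 1 if the clone carries a
supermutant C->T at site i), this module computes:

* the mutations-per-clone distribution,
* cluster fractions (>=2 mutations within an N-nt window),
* the normalised mutation covariance
  c(i,j) = <dh_i dh_j> / (sigma_i sigma_j), dh_i = h_i - <h_i>,
* the distance-dependent correlation C(d), averaging c(i,j) over all
  defined site pairs at separation d, and
* the exponential fit C(d) = exp(-d/L) whose characteristic length L
  estimates the processive scanning distance in nt.

Averages <.> run by default over multiply-mutated clones (>= 2
mutations), the ensemble the published correlation analysis uses; the
whole library is available via ``scope="all"``.  Pairs where either
site never varies (sigma = 0) are undefined and excluded, as are
diagonal elements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class CloneMutationMatrix:
    """Binary clones x C-sites indicator matrix for one strand library."""

    strand: str
    coords: np.ndarray          # duplex coordinates of the C-site columns
    matrix: np.ndarray          # shape (n_clones, n_sites), dtype bool/int
    clone_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.matrix = np.asarray(self.matrix).astype(np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.coords.size:
            raise ValueError("matrix shape does not match coordinate vector")
        if not np.all((self.matrix == 0) | (self.matrix == 1)):
            raise ValueError("matrix must be binary")
        if not self.clone_ids:
            self.clone_ids = list(range(self.matrix.shape[0]))

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, coords, strand: str,
                   clone_ids=None) -> "CloneMutationMatrix":
        """Build from a clone-call table (columns uid/clone_id, coord).

        ``coords`` lists the C-site coordinates of the strand; calls at
        other coordinates (non-C->T events) are ignored.  ``clone_ids``
        fixes the row universe (clones with zero calls included); by
        default rows are the clones present in ``calls``.
        """
        coords = np.asarray(sorted(coords), dtype=int)
        idx = {c: i for i, c in enumerate(coords)}
        id_col = "clone_id" if "clone_id" in calls else "uid"
        if clone_ids is None:
            clone_ids = sorted(calls[id_col].unique())
        rows = {cid: i for i, cid in enumerate(clone_ids)}
        mat = np.zeros((len(clone_ids), coords.size), dtype=np.int8)
        ri = calls[id_col].map(rows)
        ci = calls["coord"].map(idx)
        ok = ri.notna() & ci.notna()
        mat[ri[ok].astype(int).to_numpy(), ci[ok].astype(int).to_numpy()] = 1
        return cls(strand=strand, coords=coords, matrix=mat, clone_ids=list(clone_ids))

    def per_clone_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def restrict(self, min_mut: int = 2, max_mut: int | None = None) -> "CloneMutationMatrix":
        counts = self.per_clone_counts()
        keep = counts >= min_mut
        if max_mut is not None:
            keep &= counts <= max_mut
        return CloneMutationMatrix(strand=self.strand, coords=self.coords,
                                   matrix=self.matrix[keep],
                                   clone_ids=[cid for cid, k in zip(self.clone_ids, keep) if k])


# ---------------------------------------------------------------------------
# per-clone distribution and clusters


def mutations_per_clone(matrix: CloneMutationMatrix) -> pd.DataFrame:
    """Histogram of mutation counts over mutated clones.

    Returns columns ``n_mutations``, ``clones``, ``fraction`` (of
    mutated clones); an empty matrix yields an empty frame.  The
    fraction at ``n_mutations == 1`` is the singly-mutated fraction.
    """
    counts = matrix.per_clone_counts()
    counts = counts[counts >= 1]
    if counts.size == 0:
        return pd.DataFrame(columns=["n_mutations", "clones", "fraction"])
    vals, freq = np.unique(counts, return_counts=True)
    return pd.DataFrame({"n_mutations": vals, "clones": freq,
                         "fraction": freq / counts.size})


def singly_mutated_fraction(matrix: CloneMutationMatrix) -> float:
    hist = mutations_per_clone(matrix)
    if hist.empty:
        raise ValueError("no mutated clones")
    row = hist[hist["n_mutations"] == 1]
    return float(row["fraction"].iloc[0]) if len(row) else 0.0


def cluster_fraction(matrix: CloneMutationMatrix, window: int = 10,
                     mut_range: tuple[int, int] = (2, 5)) -> float:
    """Fraction of mutation pairs lying within an N-nt window.

    Scope is clones carrying ``mut_range`` mutations (default 2-5).  A
    pair at coordinates i < j falls within window N iff j - i <= N - 1
    (both mutations inside N consecutive nucleotides).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    sub = matrix.restrict(*mut_range)
    within = total = 0
    for row in sub.matrix:
        coords = matrix.coords[row.astype(bool)]
        for i, j in itertools.combinations(coords, 2):
            total += 1
            within += (abs(j - i) <= window - 1)
    if total == 0:
        raise ValueError("no mutation pairs in scope")
    return within / total


# ---------------------------------------------------------------------------
# covariance and distance correlation


def mutation_covariance(matrix: CloneMutationMatrix, scope: str = "multi") -> np.ndarray:
    """Normalised covariance c(i,j) over the clone library.

    ``scope='multi'`` averages over clones with >= 2 mutations (the
    published convention); ``'all'`` uses every clone.  Entries where
    sigma_i sigma_j = 0, and the diagonal, are NaN (excluded).
    """
    sub = matrix.restrict(2) if scope == "multi" else matrix
    h = sub.matrix.astype(float)
    if h.shape[0] < 2:
        raise ValueError("need at least 2 clones in scope")
    d = h - h.mean(axis=0)
    n = h.shape[0]
    cov = d.T @ d / n
    sigma = h.std(axis=0)  # population SD, matching the divide-by-n covariance
    denom = np.outer(sigma, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(c, np.nan)
    return c


def distance_correlation(c: np.ndarray, coords, d_max: int = 50) -> pd.DataFrame:
    """C(d): mean of defined c(i,j) over site pairs at separation d.

    Distances are nucleotide separations of the duplex coordinates, not
    column indices.  Distances with no defined pair are absent from the
    result.  Columns: ``d``, ``C``, ``n_pairs``.
    """
    coords = np.asarray(coords, dtype=int)
    if c.shape != (coords.size, coords.size):
        raise ValueError("covariance matrix does not match coordinates")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(coords.size):
        for j in range(i + 1, coords.size):
            d = abs(int(coords[j]) - int(coords[i]))
            if d > d_max or not np.isfinite(c[i, j]):
                continue
            sums[d] = sums.get(d, 0.0) + c[i, j]
            counts[d] = counts.get(d, 0) + 1
    rows = [(d, sums[d] / counts[d], counts[d]) for d in sorted(sums)]
    return pd.DataFrame(rows, columns=["d", "C", "n_pairs"])


@dataclass
class ExponentialFit:
    L: float                    # correlation length, nt
    amplitude: float            # 1.0 unless free_amplitude
    residual: float             # weighted RMS residual
    d_range: tuple[int, int]
    n_points: int


def fit_correlation_length(cd: pd.DataFrame, d_range: tuple[int, int] | None = None,
                           free_amplitude: bool = False) -> ExponentialFit:
    """Weighted nonlinear least-squares fit of C(d) = A * exp(-d/L).

    A is fixed to 1 by default.  Points are weighted by the number of
    contributing pairs (sigma ~ 1/sqrt(n_pairs)).  Requires >= 3
    distances with C(d) > 0 in range; refuses to fit when no C(d) is
    positive (no decay signal to measure).
    """
    df = cd.dropna(subset=["C"])
    if d_range is not None:
        df = df[(df["d"] >= d_range[0]) & (df["d"] <= d_range[1])]
    if len(df) == 0 or (df["C"] <= 0).all():
        raise ValueError("no positive C(d) in range; exponential fit refused")
    if (df["C"] > 0).sum() < 3:
        raise ValueError("need >= 3 distances with C(d) > 0 to fit")
    d = df["d"].to_numpy(dtype=float)
    y = df["C"].to_numpy(dtype=float)
    w = df["n_pairs"].to_numpy(dtype=float) if "n_pairs" in df else np.ones_like(d)
    sigma = 1.0 / np.sqrt(w)
    # log-linear initial guess from the positive points
    pos = y > 0
    slope = np.polyfit(d[pos], np.log(y[pos]), 1)[0]
    L0 = -1.0 / slope if slope < 0 else float(d.max())
    L0 = float(np.clip(L0, 1e-3, 10 * d.max()))
    if free_amplitude:
        popt, _ = curve_fit(lambda x, L, A: A * np.exp(-x / L), d, y,
                            p0=[L0, 1.0], sigma=sigma, maxfev=10000)
        L, A = float(popt[0]), float(popt[1])
    else:
        popt, _ = curve_fit(lambda x, L: np.exp(-x / L), d, y,
                            p0=[L0], sigma=sigma, maxfev=10000)
        L, A = float(popt[0]), 1.0
    if L <= 0:
        raise ValueError("fit produced a non-positive correlation length")
    resid = (y - A * np.exp(-d / L)) / sigma
    rms = float(np.sqrt(np.mean(resid ** 2)))
    rng = (int(d.min()), int(d.max())) if d_range is None else d_range
    return ExponentialFit(L=L, amplitude=A, residual=rms, d_range=rng, n_points=len(df))


def correlation_length_from_matrix(matrix: CloneMutationMatrix, scope: str = "multi",
                                   d_max: int = 50,
                                   free_amplitude: bool = False) -> tuple[ExponentialFit, pd.DataFrame]:
    """Convenience: covariance -> C(d) -> exponential fit in one call."""
    c = mutation_covariance(matrix, scope=scope)
    cd = distance_correlation(c, matrix.coords, d_max=d_max)
    fit = fit_correlation_length(cd, free_amplitude=free_amplitude)
    return fit, cd
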