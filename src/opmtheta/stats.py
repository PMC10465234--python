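"""Between-system statistics: SNR regression, image fingerprinting with a
Monte-Carlo null, and non-parametric SNR comparison.

Fingerprinting correlates each subject's source-power contrast image from one
system with every subject's image from the other system.  With n subjects
there are n² pairs: n within-subject (the diagonal) and n²−n between-subject.
The within-minus-between mean difference is tested against an empirical null
built by repeatedly re-drawing which n of the n² correlations are labelled
"within"; identification counts the rows whose maximum lies on the diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sst

from .localise import PseudoTImage

__all__ = [
    "FingerprintResult",
    "SlopeFit",
    "spatial_correlation",
    "fingerprint_matrix",
    "monte_carlo_within_between",
    "exhaustive_within_between",
    "snr_slope_fit",
    "group_slope",
    "ranksum_compare",
]


def _check_grids(a: PseudoTImage, b: PseudoTImage):
    if a.values.shape != b.values.shape or not np.allclose(a.voxel_centres, b.voxel_centres):
        raise ValueError("images are defined on different grids")


def spatial_correlation(image_a: PseudoTImage, image_b: PseudoTImage) -> float:
    """Pearson r between vectorised images over jointly valid voxels."""
    _check_grids(image_a, image_b)
    ok = image_a.valid & image_b.valid
    x, y = image_a.values[ok], image_b.values[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance image")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class FingerprintResult:
    matrix: np.ndarray  # rows: system A subjects; cols: system B subjects
    within_mean: float
    between_mean: float
    observed_difference: float
    identified: int
    n_subjects: int
    p_value: float | None = None
    n_iterations: int = 0
    seed: int | None = None

    def to_json(self, path=None):
        d = dict(
            matrix=self.matrix.tolist(),
            within_mean=self.within_mean,
            between_mean=self.between_mean,
            observed_difference=self.observed_difference,
            identified=self.identified,
            n_subjects=self.n_subjects,
            p_value=self.p_value,
            n_iterations=self.n_iterations,
            seed=self.seed,
        )
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def fingerprint_matrix(images_a: list, images_b: list) -> FingerprintResult:
    """All-pairs spatial correlations plus identification count.

    Row i, column j holds corr(subject i in system A, subject j in system B);
    a subject is identified when the row maximum falls on the diagonal (exact
    ties count as failures).
    """
    if len(images_a) != len(images_b):
        raise ValueError("need the same number of subjects in both systems")
    n = len(images_a)
    R = np.empty((n, n))
    for i, a in enumerate(images_a):
        for j, b in enumerate(images_b):
            R[i, j] = spatial_correlation(a, b)
    within = np.diag(R)
    between = R[~np.eye(n, dtype=bool)]
    identified = 0
    for i in range(n):
        row_max = R[i].max()
        if R[i, i] == row_max and np.sum(R[i] == row_max) == 1:
            identified += 1
    return FingerprintResult(
        R,
        float(within.mean()),
        float(between.mean()),
        float(within.mean() - between.mean()),
        identified,
        n,
    )


def monte_carlo_within_between(matrix, n_iter: int = 100_000, seed=None) -> float:
    """One-sided Monte-Carlo p for within-mean exceeding between-mean.

    Each iteration re-draws, uniformly without replacement, which n of the n²
    correlations count as "within"; p = (1 + #{null ≥ observed}) / (1 + n_iter).
    """
    import warnings

    if n_iter < 100:
        warnings.warn("fewer than 100 Monte-Carlo iterations", stacklevel=2)
    M = np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    n = M.shape[0]
    flat = M.ravel()
    n2 = flat.size
    observed = np.diag(M).mean() - M[~np.eye(n, dtype=bool)].mean()
    total = flat.sum()
    rng = np.random.default_rng(seed)
    exceed = 0
    block = 20_000
    tol = 1e-12 * max(1.0, float(np.max(np.abs(flat))))  # float ties count as ≥
    for s0 in range(0, n_iter, block):
        b = min(block, n_iter - s0)
        keys = rng.random((b, n2))
        sel = np.argpartition(keys, n, axis=1)[:, :n]
        within_sum = flat[sel].sum(axis=1)
        null = within_sum / n - (total - within_sum) / (n2 - n)
        exceed += int(np.sum(null >= observed - tol))
    return (1 + exceed) / (1 + n_iter)


def exhaustive_within_between(matrix) -> float:
    """Exact version of the Monte-Carlo null by full enumeration (small n)."""
    M = np.asarray(matrix, float)
    n = M.shape[0]
    flat = M.ravel()
    n2 = flat.size
    observed = np.diag(M).mean() - M[~np.eye(n, dtype=bool)].mean()
    total = flat.sum()
    tol = 1e-12 * max(1.0, float(np.max(np.abs(flat))))  # float ties count as ≥
    count = 0
    hits = 0
    for sel in combinations(range(n2), n):
        s = flat[list(sel)].sum()
        null = s / n - (total - s) / (n2 - n)
        hits += null >= observed - tol
        count += 1
    return hits / count


@dataclass
class SlopeFit:
    slope: float
    stderr: float
    intercept: float
    r: float
    p_value: float
    n: int

    def to_json(self):
        return json.dumps(
            dict(
                slope=self.slope,
                stderr=self.stderr,
                intercept=self.intercept,
                r=self.r,
                p_value=self.p_value,
                n=self.n,
            )
        )


def snr_slope_fit(snr_x, snr_y) -> SlopeFit:
    """OLS of y on x with intercept (x = reference system, y = test system).

    The slope says how the test system's per-subject SNR scales against the
    reference (slope 1 = parity); r and its two-sided p quantify how well
    individual differences are preserved.
    """
    x = np.asarray(snr_x, float)
    y = np.asarray(snr_y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples, at least 3")
    if x.std() == 0:
        raise ValueError("zero variance in predictor")
    res = sst.linregress(x, y)
    return SlopeFit(
        float(res.slope),
        float(res.stderr),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
        x.size,
    )


def group_slope(inst_a, inst_b, time, task=(0.0, 20.0), rest=(20.0, 40.0)) -> float:
    """Slope of the line through the task- and rest-window means of two
    instantaneous-SNR timecourses: Δa / Δb."""
    time = np.asarray(time, float)
    ta = (time >= task[0]) & (time < task[1])
    tr = (time >= rest[0]) & (time < rest[1])
    a = np.asarray(inst_a, float)
    b = np.asarray(inst_b, float)
    db = b[ta].mean() - b[tr].mean()
    if db == 0:
        raise ZeroDivisionError("reference timecourse has zero task-rest difference")
    return float((a[ta].mean() - a[tr].mean()) / db)


def ranksum_compare(snr_a, snr_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration for combined n ≤ 20 without ties; normal approximation
    with tie correction otherwise.
    """
    a = np.asarray(snr_a, float)
    b = np.asarray(snr_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per sample")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
    return float(sst.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
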