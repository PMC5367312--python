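"""Cluster-mass permutation inference on unit-level log-ratio series.

The test localizes condition effects in time without bin-by-bin multiple
comparisons.  Per frame, each unit's contrast score is the weighted sum of
its three condition log ratios, and a one-sample t statistic tests the
scores against zero (a within-unit design).  Frames significant at the
per-frame alpha (two-tailed) are grouped into maximal same-direction runs —
clusters — and each cluster's *mass* is the sum of its t values.  The null
distribution of the maximum absolute cluster mass is built by relabelling
the three condition series within each unit by an independent uniformly
random permutation (which respects the within-subject, within-item design
and preserves each unit's temporal structure), re-running the whole
per-frame/cluster pipeline each time.  A cluster's p-value is
(b + 1) / (n + 1), where b counts null maxima at least as large as the
cluster's |mass| (ties count toward b).  Running the analysis once over
subjects and once over items yields the p1/p2 pair reported per contrast.

For small unit counts the 6^U within-unit relabellings can be enumerated
exhaustively, in which case p = #(null >= |mass|) / 6^U with the identity
relabelling included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .aggregate import LogRatioSeries
from .design import CONDITIONS, N_CONDITIONS

#: All 6 permutations of the three condition labels; row 0 is the identity.
PERMS3 = np.array(list(itertools.permutations(range(N_CONDITIONS))), dtype=np.int64)

#: Absolute tolerance when comparing null masses with an observed |mass|,
#: so that structural ties (e.g. the identity relabelling) are counted
#: identically by independent implementations.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class Contrast:
    """A named weight vector over the canonical condition order.

    Weights must sum to zero and not all be zero.
    """

    name: str
    weights: tuple[float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_CONDITIONS,):
            raise ValueError(f"weights must have {N_CONDITIONS} entries (order {CONDITIONS})")
        if not np.isclose(w.sum(), 0.0, atol=1e-9):
            raise ValueError(f"contrast weights must sum to 0; got {w.tolist()}")
        if np.allclose(w, 0.0):
            raise ValueError("contrast weights must not all be zero")
        object.__setattr__(self, "weights", tuple(w.tolist()))


#: Average of the two two-precedent conditions versus the one-precedent
#: condition: the effect of hearing the critical object named at all.
LINGUISTIC = Contrast("linguistic", (-1.0, 0.5, 0.5))

#: One speaker-two precedents versus two speakers-two precedents: the effect
#: of the precedent being in common ground with the live speaker.
COMMON_GROUND = Contrast("common_ground", (0.0, 1.0, -1.0))


@dataclass
class FrameStatSeries:
    """Per-frame one-sample t statistics on unit contrast scores.

    ``t`` is NaN where a frame is untestable (fewer than two contributing
    units, or zero variance among scores).  ``df = n_units - 1``.
    """

    t: np.ndarray            # (n_frames,)
    n_units: np.ndarray      # (n_frames,)
    frame_starts_ms: np.ndarray
    bin_width_ms: float

    @property
    def df(self) -> np.ndarray:
        return self.n_units - 1


@dataclass
class Cluster:
    """A maximal run of consecutive same-direction significant frames."""

    start_frame: int
    end_frame: int
    direction: int           # +1 or -1
    mass: float              # sum of t over the run
    p_value: float | None = None
    start_ms: float | None = None
    end_ms: float | None = None

    def to_dict(self) -> dict:
        return {
            "start_frame": self.start_frame,
            "end_frame": self.end_frame,
            "direction": self.direction,
            "mass": self.mass,
            "p_value": self.p_value,
            "start_ms": self.start_ms,
            "end_ms": self.end_ms,
        }


def _t_from_scores(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t against 0 along the unit axis (second-to-last).

    ``scores`` has shape (..., n_units, n_frames) with NaN marking a unit
    missing at a frame.  Returns (t, n) with unit counts per frame; t is NaN
    where n < 2 or the score variance is (numerically) zero.
    """
    valid = np.isfinite(scores)
    n = valid.sum(axis=-2)
    s = np.where(valid, scores, 0.0)
    mean = s.sum(axis=-2) / np.maximum(n, 1)
    d = np.where(valid, scores - np.expand_dims(mean, -2), 0.0)
    ss = (d * d).sum(axis=-2)
    var = ss / np.maximum(n - 1, 1)
    tiny = (1e-9 * (np.abs(mean) + 1e-12)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / np.maximum(n, 1))
    t = np.where((n >= 2) & (var > tiny), t, np.nan)
    return t, n


def frame_statistics(series: LogRatioSeries, contrast: Contrast) -> FrameStatSeries:
    """Per-frame one-sample t of unit-level contrast scores against zero.

    A unit missing any condition at a frame contributes no score there (the
    NaN propagates through the weighted sum); frames with fewer than two
    units, or identical scores, are marked untestable (t = NaN).
    """
    w = np.asarray(contrast.weights)
    scores = np.einsum("k,ukf->uf", w, series.eta)
    t, n = _t_from_scores(scores)
    return FrameStatSeries(
        t=t,
        n_units=n,
        frame_starts_ms=series.frame_starts_ms.copy(),
        bin_width_ms=series.bin_width_ms,
    )


def _critical_values(n_units: np.ndarray, alpha: float) -> np.ndarray:
    """Two-tailed t critical value per frame; +inf where df < 1."""
    df = np.maximum(n_units - 1, 1)
    crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return np.where(n_units - 1 >= 1, crit, np.inf)


def detect_clusters(stats: FrameStatSeries, alpha: float = 0.05,
                    t_crit=None) -> list[Cluster]:
    """Maximal same-direction runs of frames with |t| >= the critical value.

    The critical value defaults to the two-tailed t quantile at the frame's
    df; ``t_crit`` (scalar or per-frame array) overrides it.  Cluster mass is
    the sum of t over the run.  Untestable (NaN) frames break runs.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    t = stats.t
    crit = _critical_values(stats.n_units, alpha) if t_crit is None \
        else np.broadcast_to(np.asarray(t_crit, dtype=float), t.shape)
    finite = np.isfinite(t)
    marked = finite & (np.abs(t) >= crit)
    clusters: list[Cluster] = []
    start = None
    direction = 0
    mass = 0.0
    for f in range(t.size + 1):
        ok = f < t.size and marked[f]
        sgn = 0 if not ok else (1 if t[f] > 0 else -1)
        if start is not None and (not ok or sgn != direction):
            clusters.append(_make_cluster(start, f - 1, direction, mass, stats))
            start = None
        if ok and start is None:
            start, direction, mass = f, sgn, 0.0
        if ok:
            mass += float(t[f])
    return clusters


def _make_cluster(start: int, end: int, direction: int, mass: float,
                  stats: FrameStatSeries) -> Cluster:
    return Cluster(
        start_frame=start,
        end_frame=end,
        direction=direction,
        mass=mass,
        start_ms=float(stats.frame_starts_ms[start]),
        end_ms=float(stats.frame_starts_ms[end] + stats.bin_width_ms),
    )


def max_abs_cluster_masses(t: np.ndarray, crit: np.ndarray) -> np.ndarray:
    """Maximum |cluster mass| per row of a (n_series, n_frames) t matrix.

    Rows without clusters score 0.  ``crit`` is a per-frame critical value.
    Vectorized over rows via run-boundary detection and segmented sums.
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    P, F = t.shape
    finite = np.isfinite(t)
    tt = np.where(finite, t, 0.0)
    marked = finite & (np.abs(t) >= crit)
    key = np.where(marked, np.sign(tt), 0.0).ravel()
    vals = np.where(marked, tt, 0.0).ravel()
    row = np.repeat(np.arange(P), F)
    is_start = np.ones(P * F, dtype=bool)
    is_start[1:] = (key[1:] != key[:-1]) | (row[1:] != row[:-1])
    starts = np.flatnonzero(is_start)
    sums = np.add.reduceat(vals, starts)
    seg_rows = row[starts]
    in_cluster = key[starts] != 0
    out = np.zeros(P)
    np.maximum.at(out, seg_rows[in_cluster], np.abs(sums[in_cluster]))
    return out


def _check_balanced(series: LogRatioSeries) -> None:
    all_nan = ~np.isfinite(series.eta).any(axis=2)  # (U, 3)
    if all_nan.any():
        bad = series.unit_ids[all_nan.any(axis=1)].tolist()
        raise ValueError(
            f"unbalanced design: {series.unit_kind}(s) {bad} lack data in some condition"
        )


def permute_labels(series: LogRatioSeries, rng: np.random.Generator,
                   assignments: np.ndarray | None = None) -> LogRatioSeries:
    """Relabel the three condition series within each unit.

    Each unit independently receives a uniformly random permutation of the
    condition labels, applied identically across all its frames — the eta
    values themselves are never altered, only which condition they carry.
    ``assignments`` (indices into the 6 permutations, one per unit)
    overrides the random draw; index 0 is the identity.
    """
    _check_balanced(series)
    g = rng.integers(0, len(PERMS3), size=series.n_units) if assignments is None \
        else np.asarray(assignments, dtype=np.int64)
    perm = PERMS3[g]  # (U, 3)
    rows = np.arange(series.n_units)[:, None]
    return LogRatioSeries(
        eta=series.eta[rows, perm, :],
        count_unmentioned=series.count_unmentioned[rows, perm, :],
        count_critical=series.count_critical[rows, perm, :],
        unit_ids=series.unit_ids.copy(),
        unit_kind=series.unit_kind,
        frame_starts_ms=series.frame_starts_ms.copy(),
        bin_width_ms=series.bin_width_ms,
    )


def cluster_p_value(mass: float, null_max_masses: np.ndarray,
                    exhaustive: bool = False) -> float:
    """Permutation p for one cluster against the null max-|mass| sample.

    Monte-Carlo sampling uses (b + 1) / (n + 1) with ties counted toward b;
    exhaustive enumeration (identity included in the null) uses b / n.
    """
    null = np.asarray(null_max_masses, dtype=float)
    b = int((null >= abs(mass) - TIE_TOL).sum())
    n = null.size
    return b / n if exhaustive else (b + 1) / (n + 1)


@dataclass
class PermutationReport:
    """Observed clusters plus the permutation null for one contrast/unit kind."""

    contrast: Contrast
    unit_kind: str
    observed: FrameStatSeries
    clusters: list[Cluster]
    null_max_masses: np.ndarray
    n_permutations: int
    alpha: float
    seed: int | None
    exhaustive: bool = False

    @property
    def min_p(self) -> float | None:
        ps = [c.p_value for c in self.clusters if c.p_value is not None]
        return min(ps) if ps else None

    def significant_clusters(self, level: float | None = None) -> list[Cluster]:
        level = self.alpha if level is None else level
        return [c for c in self.clusters if c.p_value is not None and c.p_value <= level]

    def onset_ms(self, level: float | None = None) -> float | None:
        """Start time of the earliest significant cluster, or None."""
        sig = self.significant_clusters(level)
        return min(c.start_ms for c in sig) if sig else None

    def to_dict(self) -> dict:
        return {
            "contrast": {"name": self.contrast.name, "weights": list(self.contrast.weights)},
            "unit_kind": self.unit_kind,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "clusters": [c.to_dict() for c in self.clusters],
            "onset_ms": self.onset_ms(),
        }


def permutation_test(series: LogRatioSeries, contrast: Contrast,
                     alpha: float = 0.05, n_permutations: int = 1000,
                     seed=None, exhaustive: bool = False,
                     _chunk: int = 200_000) -> PermutationReport:
    """Cluster-mass permutation test of one contrast on one unit kind.

    Runs the per-frame t / cluster-detection pipeline on the observed data,
    then on ``n_permutations`` within-unit relabellings (or, with
    ``exhaustive=True``, on all ``6**n_units`` of them), recording each
    run's maximum absolute cluster mass (0 when no cluster forms).  Each
    observed cluster receives a p-value against that null sample.
    Deterministic for a fixed seed; the input series is never mutated.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    _check_balanced(series)
    U, _, F = series.eta.shape
    w = np.asarray(contrast.weights)

    # Contrast scores under each of the 6 relabellings, per unit:
    # s6[u, g, f] = sum_k w_k * eta[u, perm_g[k], f].
    eta6 = series.eta[:, PERMS3, :]                      # (U, 6, 3, F)
    s6 = np.einsum("k,ugkf->ugf", w, eta6)               # (U, 6, F)

    obs_t, obs_n = _t_from_scores(s6[:, 0, :])
    observed = FrameStatSeries(
        t=obs_t, n_units=obs_n,
        frame_starts_ms=series.frame_starts_ms.copy(),
        bin_width_ms=series.bin_width_ms,
    )
    clusters = detect_clusters(observed, alpha)
    crit = _critical_values(obs_n, alpha)

    if exhaustive:
        n_total = len(PERMS3) ** U
        if n_total > 500_000:
            raise ValueError(
                f"exhaustive enumeration of {n_total} relabellings is too large; "
                f"use Monte-Carlo sampling"
            )
        assign_iter = itertools.product(range(len(PERMS3)), repeat=U)
        seed_used = None
    else:
        n_total = int(n_permutations)
        rng = np.random.default_rng(seed)
        assign_iter = None
        seed_used = seed if isinstance(seed, (int, np.integer)) else None

    null_max = np.empty(n_total)
    rows = np.arange(U)[None, :]
    chunk_rows = max(1, _chunk // max(U * F, 1))
    done = 0
    while done < n_total:
        m = min(chunk_rows, n_total - done)
        if exhaustive:
            G = np.fromiter(
                itertools.chain.from_iterable(itertools.islice(assign_iter, m)),
                dtype=np.int64, count=m * U,
            ).reshape(m, U)
        else:
            G = rng.integers(0, len(PERMS3), size=(m, U))
        scores = s6[rows, G, :]                          # (m, U, F)
        t_null, _ = _t_from_scores(scores)
        null_max[done:done + m] = max_abs_cluster_masses(t_null, crit)
        done += m

    for c in clusters:
        c.p_value = cluster_p_value(c.mass, null_max, exhaustive=exhaustive)

    return PermutationReport(
        contrast=contrast,
        unit_kind=series.unit_kind,
        observed=observed,
        clusters=clusters,
        null_max_masses=null_max,
        n_permutations=n_total,
        alpha=alpha,
        seed=seed_used,
        exhaustive=exhaustive,
    )
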