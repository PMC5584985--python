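"""Statistics used across the pipeline.

Paired t and Pearson correlation are thin, validated wrappers around
scipy.stats.  The pieces implemented here because no standard routine
exposes them in the required form are:

* :func:`fisher_compare` — comparison of two independent Pearson
  correlations through the Fisher r-to-z transform;
* :func:`sidak_alpha` — Sidak-corrected per-comparison alpha;
* :func:`ratio_sem` — error propagation for the SEM of a log2 ratio of
  two group means, from their coefficients of variation;
* :func:`dip_statistic` / :func:`dip_test` — Hartigan's dip statistic
  for unimodality with a Monte-Carlo p-value against the uniform null.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atanh, log2, sqrt

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_t",
    "pearson",
    "fisher_compare",
    "sidak_alpha",
    "ratio_sem",
    "dip_statistic",
    "dip_test",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is the test statistic (t, r, z or dip D depending on the
    test), ``df`` the degrees of freedom (NaN where the test has none), ``p``
    the p-value for the stated number of ``tails``.
    """

    statistic: float
    df: float
    p: float
    tails: str = "two"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.tails not in ("one", "two"):
            raise ValueError(f"tails must be 'one' or 'two', got {self.tails!r}")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def paired_t(x, y) -> TestResult:
    """Paired two-sided t-test on matched samples ``x`` and ``y``.

    Differences ``y - x`` are tested against zero mean with ``df = n - 1``.
    A degenerate sample with zero-variance, zero-mean differences (x == y)
    returns ``t = 0, p = 1``; zero variance around a non-zero mean is an
    error because the t statistic is unbounded.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = y - x
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return TestResult(statistic=0.0, df=float(n - 1), p=1.0)
        raise ValueError("differences have zero variance but non-zero mean")
    res = sps.ttest_rel(y, x)
    return TestResult(statistic=float(res.statistic), df=float(n - 1), p=float(res.pvalue))


def pearson(x, y) -> TestResult:
    """Pearson correlation with two-sided p and ``df = n - 2``."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), df=float(n - 2), p=float(p))


def fisher_compare(r1: float, n1: int, r2: float, n2: int, tails: str = "two") -> TestResult:
    """Compare two independent correlations via the Fisher r-to-z transform.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); the one-tailed
    p-value is the normal tail beyond \\|z\\|, the two-tailed p doubles it.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
        if n < 4:
            raise ValueError("each sample needs n >= 4")
    z = (atanh(r1) - atanh(r2)) / sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p_one = float(sps.norm.sf(abs(z)))
    p = p_one if tails == "one" else min(1.0, 2.0 * p_one)
    return TestResult(statistic=float(z), df=float("nan"), p=p, tails=tails)


def sidak_alpha(alpha: float, m: int) -> float:
    """Sidak-corrected per-comparison alpha: ``1 − (1 − alpha)^(1/m)``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def ratio_sem(mean_a: float, cv_a: float, mean_b: float, cv_b: float, n: int) -> float:
    """SEM of the log2 ratio of two group means.

    Computes ``|log2(mean_a / mean_b)| * sqrt((cv_a^2 + cv_b^2) / n)`` where
    the cv's are the groups' coefficients of variation and ``n`` the number
    of paired observations behind the ratio.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("means must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv_a < 0 or cv_b < 0:
        raise ValueError("coefficients of variation must be non-negative")
    return abs(log2(mean_a / mean_b)) * sqrt((cv_a**2 + cv_b**2) / n)


# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------


def _one_sided_dev(px: np.ndarray, py_hull: np.ndarray, py_other: np.ndarray) -> float:
    """Max of ``py_other`` above the lower convex hull of ``(px, py_hull)``.

    ``px`` must be sorted.  Duplicate abscissae keep only their lowest hull
    corner (the minorant passes under the stack).
    """
    if px.size == 0:
        return 0.0
    if px.size > 1:
        keep = np.empty(px.size, dtype=bool)
        keep[0] = True
        keep[1:] = px[1:] > px[:-1]
    else:
        keep = np.ones(1, dtype=bool)
    hx = px[keep]
    hy = py_hull[keep]
    hull: list[int] = [0]
    for i in range(1, hx.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b if it lies on or above the chord a -> i
            if (hy[b] - hy[a]) * (hx[i] - hx[a]) >= (hy[i] - hy[a]) * (hx[b] - hx[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    idx = np.asarray(hull, dtype=np.intp)
    minorant = np.interp(px, hx[idx], hy[idx])
    return float(np.max(py_other - minorant))


_S_BIG = 1e15  # stand-in for an unbounded slope in the frontier sweep


def _pl_clip(sv: list, vv: list, level: float, lower: bool) -> tuple[list, list]:
    """Clip a piecewise-linear curve at ``level`` (max if lower else min)."""
    ns = [sv[0]]
    nv = [max(vv[0], level) if lower else min(vv[0], level)]
    for k in range(1, len(sv)):
        a, b = vv[k - 1], vv[k]
        if (a - level) * (b - level) < 0.0:
            sc = sv[k - 1] + (level - a) * (sv[k] - sv[k - 1]) / (b - a)
            ns.append(sc)
            nv.append(level)
        ns.append(sv[k])
        nv.append(max(b, level) if lower else min(b, level))
    return ns, nv


def _pl_domain(sv: list, vv: list, level: float, below: bool) -> tuple[float, float] | None:
    """The s-interval where the curve is <= level (below) or >= level.

    Assumes the qualifying region is a single interval (curve convex for
    sub-level queries, concave for super-level queries).
    """

    def ok(v: float) -> bool:
        return v <= level if below else v >= level

    s0 = s1 = None
    for k in range(len(sv)):
        if ok(vv[k]):
            if s0 is None:
                if k > 0 and not ok(vv[k - 1]):
                    s0 = sv[k - 1] + (level - vv[k - 1]) * (sv[k] - sv[k - 1]) / (
                        vv[k] - vv[k - 1]
                    )
                else:
                    s0 = sv[k]
            s1 = sv[k]
        elif s0 is not None:
            s1 = sv[k - 1] + (level - vv[k - 1]) * (sv[k] - sv[k - 1]) / (
                vv[k] - vv[k - 1]
            )
            break
    if s0 is None:
        return None
    return s0, s1


def _pl_trim(sv: list, vv: list, s0: float, s1: float) -> tuple[list, list]:
    """Restrict a piecewise-linear curve to the s-interval [s0, s1]."""
    ns, nv = [s0], [float(np.interp(s0, sv, vv))]
    for k in range(len(sv)):
        if s0 < sv[k] < s1:
            ns.append(sv[k])
            nv.append(vv[k])
    if s1 > s0:
        ns.append(s1)
        nv.append(float(np.interp(s1, sv, vv)))
    return ns, nv


def _sweep_min_end(x: np.ndarray, lbox: np.ndarray, ubox: np.ndarray) -> np.ndarray:
    """Minimal attainable value at each point of a convex increasing function
    threading the per-point boxes ``[lbox_i, ubox_i]``.

    The reachable (value, last-slope) pairs after each point form a convex
    set; its lower frontier phi(s) (convex, minimal value with final slope
    <= s) and upper frontier psi(s) (concave, maximal value) are carried as
    piecewise-linear curves.  Propagating over a gap takes the monotone
    envelopes (slopes may only grow), adds s*gap, clips at the next box and
    restricts the slope domain to where the box can be met.  Returns +inf
    from the first point where no function survives.
    """
    m = x.size
    out = np.full(m, np.inf)
    if m == 0 or lbox[0] > ubox[0]:
        return out
    sv = [0.0, _S_BIG]
    phi = [lbox[0], lbox[0]]
    sp = [0.0, _S_BIG]
    psi = [ubox[0], ubox[0]]
    out[0] = lbox[0]
    for i in range(1, m):
        gap = x[i] - x[i - 1]
        if gap > 0.0:
            # phi: non-increasing envelope, truncated at the argmin vertex
            k = min(range(len(phi)), key=phi.__getitem__)
            sv, phi = sv[: k + 1], phi[: k + 1]
            if sv[-1] < _S_BIG:
                sv.append(_S_BIG)
                phi.append(phi[-1])
            phi = [v + s * gap for v, s in zip(phi, sv)]
            # psi: non-decreasing envelope, truncated at the argmax vertex
            k = max(range(len(psi)), key=psi.__getitem__)
            sp, psi = sp[: k + 1], psi[: k + 1]
            if sp[-1] < _S_BIG:
                sp.append(_S_BIG)
                psi.append(psi[-1])
            psi = [v + s * gap for v, s in zip(psi, sp)]
        li, ui = lbox[i], ubox[i]
        if li > ui:
            return out
        # the value slice at slope s is [max(phi, li), min(psi, ui)]; it is
        # non-empty where phi <= ui and psi >= li
        dom_a = _pl_domain(sv, phi, ui, below=True)
        dom_b = _pl_domain(sp, psi, li, below=False)
        if dom_a is None or dom_b is None:
            return out
        s0 = max(dom_a[0], dom_b[0])
        s1 = min(dom_a[1], dom_b[1])
        if s0 > s1:
            return out
        sv, phi = _pl_trim(sv, phi, s0, s1)
        sp, psi = _pl_trim(sp, psi, s0, s1)
        sv, phi = _pl_clip(sv, phi, li, lower=True)
        sp, psi = _pl_clip(sp, psi, ui, lower=False)
        out[i] = min(phi)
    return out


def _unimodal_tube_feasible(xs: np.ndarray, d: float) -> bool:
    """Whether some unimodal CDF stays within sup-distance d of the ECDF."""
    n = xs.size
    lo = np.arange(n) / n
    up = lo + 1.0 / n
    lbox = np.maximum(up - d, 0.0)
    ubox = np.minimum(lo + d, 1.0)
    min_end = _sweep_min_end(xs, lbox, ubox)
    # the concave right side reflects onto a convex sweep via x -> -x, G -> 1-G
    min_end_r = _sweep_min_end(-xs[::-1], (1.0 - ubox)[::-1], (1.0 - lbox)[::-1])
    max_start = 1.0 - min_end_r[::-1]
    if np.isfinite(min_end_r[-1]):  # mode before the first point
        return True
    if np.isfinite(min_end[-1]) and min_end[-1] <= 1.0:  # mode after the last
        return True
    return bool(np.any(min_end[:-1] <= max_start[1:]))


def _min_sup_dip(xs: np.ndarray) -> float:
    """Exact dip of a sorted sample as min-sup distance to unimodal CDFs.

    With the mode between order statistics j and j+1, a unimodal CDF is
    convex over the first j points and concave over the rest.  Half the
    flank deviations from the restricted convex minorant / concave majorant
    give a lower bound on the dip for that split, and a parallel-shift
    construction of the two flank fits gives an achievable upper bound; the
    exact value between them is located by bisection on the tube half-width
    with an explicit feasibility sweep.
    """
    n = xs.size
    lo = np.arange(n) / n
    up = lo + 1.0 / n
    def left_dev(j: int) -> float:
        return _one_sided_dev(xs[:j], lo[:j], up[:j]) if j else 0.0

    def right_dev(j: int) -> float:
        if j == n:
            return 0.0
        return _one_sided_dev(-xs[j:][::-1], -up[j:][::-1], -lo[j:][::-1])

    # left_dev is non-decreasing in the split and right_dev non-increasing,
    # so max(left, right)/2 is V-shaped; its minimum is a valid lower bound
    # on the dip, and the parallel-shift construction at the same split (the
    # glue term pays for joining the two flank fits) is attainable
    lo_j, hi_j = 0, n
    while lo_j < hi_j:
        mid = (lo_j + hi_j) // 2
        if left_dev(mid) >= right_dev(mid):
            hi_j = mid
        else:
            lo_j = mid + 1
    lb, ub = np.inf, 0.5
    for j in {max(0, lo_j - 1), lo_j, min(n, lo_j + 1)}:
        a, b = left_dev(j), right_dev(j)
        lb = min(lb, max(a, b) / 2.0)
        ub = min(ub, max(a / 2.0, b / 2.0, (a + b) / 2.0 - 1.0 / n))
    lb = max(lb, 0.5 / n)
    if ub - lb <= 1e-13:
        return ub
    while ub - lb > 1e-13:
        mid = 0.5 * (lb + ub)
        if _unimodal_tube_feasible(xs, mid):
            ub = mid
        else:
            lb = mid
    return ub


def dip_statistic(x) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    The dip is the smallest sup-norm distance between the empirical CDF and
    the set of unimodal CDFs; it is at least 1/(2n) for any sample and is
    invariant under monotone affine transforms.
    """
    xs = np.sort(_as_1d(x, "x"))
    n = xs.size
    if n < 4:
        raise ValueError("dip statistic needs n >= 4")
    if xs[0] == xs[-1]:
        raise ValueError("degenerate sample: all values identical")
    return _min_sup_dip(xs)


def dip_test(x, n_boot: int = 10_000, seed: int | None = None) -> TestResult:
    """Hartigan's dip test of unimodality.

    The p-value is the Monte-Carlo probability that a uniform sample of the
    same size attains a dip at least as large as observed (the uniform is
    the asymptotically least favourable unimodal null).  ``df`` reports the
    sample size.
    """
    xs = _as_1d(x, "x")
    n = xs.size
    d = dip_statistic(xs)
    rng = np.random.default_rng(seed)
    # a null sample counts against the observed dip iff its own dip is at
    # least d, i.e. iff no unimodal CDF fits it inside a tube of (slightly
    # less than) d -- one feasibility sweep per sample, no bisection
    ge = 0
    thr = d - 1e-12
    for _ in range(n_boot):
        u = np.sort(rng.random(n))
        if not _unimodal_tube_feasible(u, thr):
            ge += 1
    # add-one correction keeps p strictly positive at finite n_boot
    p = (1.0 + ge) / (n_boot + 1.0)
    return TestResult(statistic=d, df=float(n), p=p)
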