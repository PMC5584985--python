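"""High/low-firing classification of SPN calcium responses.

Baseline evoked calcium-transient amplitudes are separated into two
clusters with a univariate two-component Gaussian mixture (the only
user-specified input is k = 2): the larger-mean component corresponds to
multi-action-potential ("high-firing") responses and the smaller-mean
component to single-AP ("low-firing") responses.  The module also
compares the mixture classification against a fixed physiological
amplitude cutoff, quantifies drug effects per cluster with paired
t-tests, and regresses the drug effect on baseline amplitude.

A loader is provided for the deposited MATLAB source-data layout
(``GMMs`` plus N×2 ``dSPNs_high``/``dSPNs_low``/``iSPNs_high``/
``iSPNs_low`` matrices with pre-drug amplitudes in column 1 and paired
post-drug measurements in column 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.io import loadmat
from sklearn.mixture import GaussianMixture

from . import stats as _stats

__all__ = [
    "GMM2",
    "ClassifiedAmplitudes",
    "fit_gmm2",
    "classify_high_low",
    "cutoff_agreement",
    "drug_effect",
    "baseline_effect_regression",
    "load_figure_source",
]


@dataclass
class GMM2:
    """Two-component univariate Gaussian mixture, ordered low then high."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    cell_type: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.weights.size == self.means.size == self.sds.size == 2):
            raise ValueError("GMM2 needs exactly two components")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component SDs must be positive")
        order = np.argsort(self.means)
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.sds = self.sds[order]

    def posterior_high(self, x) -> np.ndarray:
        """Posterior probability that each amplitude belongs to the
        larger-mean ("high") component."""
        x = np.asarray(x, dtype=float)
        log_lo = np.log(self.weights[0]) + sps.norm.logpdf(x, self.means[0], self.sds[0])
        log_hi = np.log(self.weights[1]) + sps.norm.logpdf(x, self.means[1], self.sds[1])
        m = np.maximum(log_lo, log_hi)
        p_lo = np.exp(log_lo - m)
        p_hi = np.exp(log_hi - m)
        return p_hi / (p_lo + p_hi)


@dataclass
class ClassifiedAmplitudes:
    """Paired pre/post amplitudes with their baseline-derived labels."""

    amplitudes_pre: np.ndarray
    amplitudes_post: np.ndarray
    labels: np.ndarray  # "high" | "low", per cell
    cell_type: str | None = None

    def __post_init__(self) -> None:
        self.amplitudes_pre = np.asarray(self.amplitudes_pre, dtype=float)
        self.amplitudes_post = np.asarray(self.amplitudes_post, dtype=float)
        self.labels = np.asarray(self.labels)
        if not (
            self.amplitudes_pre.size == self.amplitudes_post.size == self.labels.size
        ):
            raise ValueError("pre, post and labels must align")


def fit_gmm2(amplitudes, seed: int = 0, restarts: int = 50, cell_type: str | None = None) -> GMM2:
    """EM fit of a two-component univariate Gaussian mixture with unequal
    variances; the best of ``restarts`` initializations by log-likelihood
    is kept."""
    x = np.asarray(amplitudes, dtype=float).reshape(-1, 1)
    if x.size < 4:
        raise ValueError("need at least 4 amplitudes to fit two components")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate input: all amplitudes identical")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="diag",
        n_init=restarts,
        random_state=seed,
        reg_covar=1e-10,
    ).fit(x)
    return GMM2(
        weights=gm.weights_,
        means=gm.means_.ravel(),
        sds=np.sqrt(gm.covariances_.ravel()),
        cell_type=cell_type,
    )


def classify_high_low(model: GMM2, amplitudes) -> np.ndarray:
    """Assign each amplitude to the component with the larger posterior;
    the larger-mean component is "high" and posterior ties go to "low"."""
    p_hi = model.posterior_high(amplitudes)
    return np.where(p_hi > 0.5, "high", "low")


def cutoff_agreement(labels, amplitudes, cutoff: float = 0.05) -> float:
    """Percent agreement between the mixture labels and a fixed amplitude
    cutoff (amplitude >= cutoff counts as high)."""
    labels = np.asarray(labels)
    amps = np.asarray(amplitudes, dtype=float)
    if labels.size == 0 or labels.size != amps.size:
        raise ValueError("labels and amplitudes must align and be non-empty")
    cut_labels = np.where(amps >= cutoff, "high", "low")
    return 100.0 * float(np.mean(labels == cut_labels))


@dataclass
class GroupEffect:
    """Drug effect within one label group."""

    n: int
    mean_delta: float
    test: _stats.TestResult | None  # None when the group is too small
    skipped: bool = field(init=False)

    def __post_init__(self) -> None:
        self.skipped = self.test is None


def drug_effect(cls: ClassifiedAmplitudes) -> dict[str, GroupEffect]:
    """Paired two-sided t-test of post vs pre within each label group,
    with the mean post-pre change; groups with n < 2 are skipped."""
    out: dict[str, GroupEffect] = {}
    for label in ("high", "low"):
        mask = cls.labels == label
        pre = cls.amplitudes_pre[mask]
        post = cls.amplitudes_post[mask]
        if pre.size < 2:
            out[label] = GroupEffect(n=int(pre.size), mean_delta=float("nan"), test=None)
            continue
        out[label] = GroupEffect(
            n=int(pre.size),
            mean_delta=float(np.mean(post - pre)),
            test=_stats.paired_t(pre, post),
        )
    return out


@dataclass
class RegressionResult:
    r: float
    slope: float
    intercept: float
    p: float
    df: float


def baseline_effect_regression(pre, post) -> RegressionResult:
    """Pearson correlation and least-squares line of the drug effect
    (post − pre) against the baseline amplitude."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 3:
        raise ValueError("need paired pre/post with n >= 3")
    if np.ptp(pre) == 0.0:
        raise ValueError("baseline amplitudes have zero variance")
    delta = post - pre
    res = _stats.pearson(pre, delta)
    slope, intercept = np.polyfit(pre, delta, 1)
    return RegressionResult(
        r=res.statistic, slope=float(slope), intercept=float(intercept), p=res.p, df=res.df
    )


def _flatten_mat(v) -> np.ndarray:
    return np.asarray(v, dtype=float)


def load_figure_source(path) -> dict:
    """Load the deposited MATLAB source-data file for the population
    analysis.

    Returns a dict with the four N×2 amplitude matrices
    (``dSPNs_high``, ``dSPNs_low``, ``iSPNs_high``, ``iSPNs_low``; pre in
    column 1, post in column 2) and, when parseable, the fitted mixture
    parameters under ``GMMs`` as :class:`GMM2` objects keyed by cell
    type.
    """
    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    out: dict = {}
    for key in ("dSPNs_high", "dSPNs_low", "iSPNs_high", "iSPNs_low"):
        if key not in raw:
            raise KeyError(f"missing field {key!r} in {path}")
        arr = _flatten_mat(raw[key])
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.shape[1] != 2:
            raise ValueError(f"{key} must be N x 2 (pre, post)")
        out[key] = arr
    if "GMMs" in raw:
        gmms = {}
        node = raw["GMMs"]
        for cell_type in ("dSPNs", "iSPNs"):
            sub = getattr(node, cell_type, None)
            if sub is None:
                continue
            gmms[cell_type] = GMM2(
                weights=_flatten_mat(sub.weights).ravel(),
                means=_flatten_mat(sub.means).ravel(),
                sds=np.sqrt(_flatten_mat(sub.variances).ravel()),
                cell_type=cell_type,
            )
        if gmms:
            out["GMMs"] = gmms
    return out
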