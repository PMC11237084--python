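"""Population activity statistics: hyperactivity classification, cumulative
rate distributions, baseline-normalized condition effects, and the
non-parametric test battery (Wilcoxon signed-rank / rank-sum, Kruskal-Wallis
with Dunn-Sidak post-hoc, two-sample Kolmogorov-Smirnov).

A neuron is hyperactive when it fires strictly more than 20 calcium
transients per minute.  For condition comparisons the statistical unit is the
subject (mouse or slice): each subject contributes the mean rate over its
neurons, and conditions are paired within subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidConfigError, NormalizationError

log = logging.getLogger(__name__)

HYPERACTIVITY_THRESHOLD = 20.0  # transients/min, strict inequality


@dataclass
class NeuronRecord:
    """Per-neuron, per-condition quantification."""

    neuron_id: int
    condition: str
    rate: float                  # transients/min
    auc: float | None = None     # df/f * s
    events: list = field(default_factory=list)
    hyperactive: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InvalidConfigError("rate must be >= 0")
        self.hyperactive = classify_hyperactive(self.rate)


@dataclass
class RecordingSession:
    """Paired per-subject records: the same neurons under every condition."""

    subject_id: str
    genotype: str
    treatment: str
    records: dict[str, list[NeuronRecord]]  # condition -> records

    def __post_init__(self) -> None:
        ids = None
        for condition, recs in self.records.items():
            these = sorted(r.neuron_id for r in recs)
            if ids is None:
                ids = these
            elif these != ids:
                raise InvalidConfigError(
                    f"condition {condition!r} has a different neuron set; "
                    "sessions must be paired"
                )

    def rates(self, condition: str) -> np.ndarray:
        return np.array([r.rate for r in self.records[condition]])

    def mean_rate(self, condition: str) -> float:
        return float(self.rates(condition).mean())


@dataclass
class StatResult:
    """Outcome of one statistical comparison (always two-sided)."""

    test: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    sidedness: str = "two-sided"
    note: str = ""
    posthoc: list["StatResult"] | None = None
    groups: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidConfigError("p-value outside [0, 1]")


def classify_hyperactive(rate: float, threshold: float = HYPERACTIVITY_THRESHOLD) -> bool:
    """True iff ``rate`` is strictly greater than the threshold (20/min)."""
    if rate < 0:
        raise InvalidConfigError(f"rate must be >= 0, got {rate}")
    return rate > threshold


def fraction_hyperactive(
    session: RecordingSession | None = None,
    condition: str | None = None,
    rates: np.ndarray | list[float] | None = None,
    threshold: float = HYPERACTIVITY_THRESHOLD,
) -> float:
    """Percentage of hyperactive neurons, from a session condition or raw rates."""
    if rates is None:
        if session is None or condition is None:
            raise InvalidConfigError("pass either a session+condition or raw rates")
        rates = session.rates(condition)
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise InsufficientDataError("fraction_hyperactive needs >= 1 neuron")
    flags = [classify_hyperactive(r, threshold) for r in rates]
    return 100.0 * sum(flags) / rates.size


@dataclass
class EmpiricalCDF:
    """Right-continuous ECDF over observed rates: P(X <= x)."""

    x: np.ndarray  # sorted unique values
    p: np.ndarray  # cumulative probability at each x

    def __call__(self, query: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.x, np.asarray(query, dtype=float), side="right")
        out = np.concatenate([[0.0], self.p])[idx]
        return out if np.ndim(query) else float(out)


def cumulative_distribution(rates: np.ndarray | list[float]) -> EmpiricalCDF:
    """Empirical cumulative distribution of neuronal activity rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise InsufficientDataError("cumulative_distribution needs >= 1 rate")
    x, counts = np.unique(rates, return_counts=True)
    return EmpiricalCDF(x=x, p=np.cumsum(counts) / rates.size)


def normalize_to_baseline(
    session: RecordingSession, condition: str, baseline: str = "baseline"
) -> float:
    """Subject-level activity in ``condition`` as % of mean baseline activity:
    100 x mean(rate_condition) / mean(rate_baseline)."""
    if baseline not in session.records:
        raise InvalidConfigError(f"session has no {baseline!r} condition")
    base = session.mean_rate(baseline)
    if base == 0:
        raise NormalizationError(
            f"subject {session.subject_id}: zero mean baseline rate; "
            "normalization undefined"
        )
    return 100.0 * session.mean_rate(condition) / base


def _dunn_sidak(groups: list[np.ndarray], labels: list[str]) -> list[StatResult]:
    """Dunn's pairwise rank comparison after Kruskal-Wallis, Sidak-adjusted."""
    all_values = np.concatenate(groups)
    n_total = all_values.size
    ranks = sps.rankdata(all_values)
    # tie correction term for the rank variance
    _, counts = np.unique(all_values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    splits = np.cumsum([g.size for g in groups])[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    m = len(groups) * (len(groups) - 1) // 2
    out: list[StatResult] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term)
                * (1.0 / groups[i].size + 1.0 / groups[j].size)
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            p_adj = float(min(1.0, 1.0 - (1.0 - min(p_raw, 1.0)) ** m))
            out.append(StatResult(
                test="dunn-sidak", statistic=float(z), p_value=p_adj,
                n_per_group=[int(groups[i].size), int(groups[j].size)],
                note=f"raw p={p_raw:.4g}, m={m}",
                groups=(labels[i], labels[j]),
            ))
    return out


def compare(
    groups: list[np.ndarray] | list[list[float]],
    design: str,
    labels: list[str] | None = None,
) -> StatResult:
    """Two-sided non-parametric comparison matched to the study design.

    * ``paired`` — Wilcoxon signed-rank on two equal-length paired vectors;
      exact null for n <= 25 without ties or zero differences, normal
      approximation otherwise.
    * ``unpaired`` — Wilcoxon rank-sum (Mann-Whitney U).
    * ``multi-group`` — Kruskal-Wallis across >= 3 groups, with Dunn pairwise
      post-hoc comparisons under Sidak correction attached to the result.
    * ``distribution`` — two-sample two-sided Kolmogorov-Smirnov.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    labels = labels or [f"group{i}" for i in range(len(arrays))]
    if any(a.size < 2 for a in arrays):
        raise InsufficientDataError("every group needs at least 2 observations")
    ns = [int(a.size) for a in arrays]

    if design == "paired":
        if len(arrays) != 2 or arrays[0].size != arrays[1].size:
            raise InvalidConfigError("paired design needs two equal-length vectors")
        diffs = arrays[0] - arrays[1]
        nonzero = diffs[diffs != 0]
        ties = np.unique(np.abs(nonzero)).size < nonzero.size
        has_zeros = nonzero.size < diffs.size
        note = ""
        if nonzero.size < 2:
            raise InsufficientDataError("fewer than 2 non-zero paired differences")
        if arrays[0].size <= 25 and not ties and not has_zeros:
            method = "exact"
        else:
            method = "approx"
            if ties or has_zeros:
                note = "ties/zeros present: mid-ranks with normal approximation"
                log.info("signed-rank: %s", note)
        res = sps.wilcoxon(arrays[0], arrays[1], alternative="two-sided", method=method)
        return StatResult("wilcoxon-signed-rank", float(res.statistic),
                          float(res.pvalue), ns, note=note)

    if design == "unpaired":
        if len(arrays) != 2:
            raise InvalidConfigError("unpaired design needs exactly two groups")
        res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided",
                               method="auto")
        return StatResult("wilcoxon-rank-sum", float(res.statistic),
                          float(res.pvalue), ns)

    if design == "multi-group":
        if len(arrays) < 3:
            raise InvalidConfigError("multi-group design needs >= 3 groups")
        res = sps.kruskal(*arrays)
        return StatResult("kruskal-wallis", float(res.statistic), float(res.pvalue),
                          ns, posthoc=_dunn_sidak(arrays, labels))

    if design == "distribution":
        if len(arrays) != 2:
            raise InvalidConfigError("distribution design needs exactly two samples")
        res = sps.ks_2samp(arrays[0], arrays[1], alternative="two-sided")
        return StatResult("kolmogorov-smirnov", float(res.statistic),
                          float(res.pvalue), ns)

    raise InvalidConfigError(f"unknown design {design!r}")
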