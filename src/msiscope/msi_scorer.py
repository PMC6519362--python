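"""Control-cohort Beta modelling and sample scoring.

The classifier works on one number per marker per sample: the fraction of
consensus families whose repeat length equals the reference (WT) length.
In mismatch-repair-proficient blood this fraction sits near 1, with
marker-specific technical variation; constitutional mismatch repair
deficiency (CMMRD) depresses it at many markers simultaneously, each by a
small amount.

Model: for each marker, the control cohort's WT frequencies are modelled as
Beta(alpha_m, beta_m). A sample's observed frequency x_m is converted to the
lower-tail probability p_m = I_x(alpha_m, beta_m) — the probability that a
control draw is at most the observation, so depressed WT frequency means
small p_m. The per-marker probabilities are combined with Fisher's method,

    X^2 = -2 * sum_m ln p_m   ~   chi^2 with 2k degrees of freedom under H0,

where k counts the markers actually included (QC-passed and modelled).
The reported score is -log10 of the combined upper-tail probability, so
score >= 1.30 marks a sample with < 5% probability of coming from the
control population, and score >= 2.00 the corresponding 1% threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InvalidMomentsError,
    ParseError,
    UnscorableSampleError,
)
from .panel_io import MarkerCounts, _format_metadata, _read_lines

__all__ = [
    "ControlModel",
    "MarkerResult",
    "SampleScore",
    "fit_control_model",
    "fit_beta_moments",
    "marker_tail_probability",
    "empirical_tail_probability",
    "fisher_combine",
    "score_from_probability",
    "classify",
    "score_sample",
    "score_frequency_matrix",
    "write_control_model",
    "read_control_model",
    "write_score_report",
    "read_score_report",
    "THRESHOLD_LENIENT",
    "THRESHOLD_CONSERVATIVE",
    "DEFAULT_CLAMP_EPSILON",
    "PROBABILITY_FLOOR",
]

#: Score thresholds equivalent to 5% and 1% probability that a sample is
#: drawn from the control population (score = -log10 p).
THRESHOLD_LENIENT = 1.30
THRESHOLD_CONSERVATIVE = 2.00

#: Observed frequencies are clamped into [eps, 1 - eps] before any Beta
#: operation: exact 1.0 is common in controls and the Beta log-density is
#: unbounded at the support boundary.
DEFAULT_CLAMP_EPSILON = 1e-6

#: Floor for per-marker and combined probabilities before taking logs.
PROBABILITY_FLOOR = 1e-300


@dataclass(frozen=True)
class ControlModel:
    """Per-marker Beta(alpha, beta) parameters fitted on a control cohort."""

    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    n_controls: int
    fit_method: str = "moments"
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON
    panel_hash: str | None = None
    #: training frequencies, kept only when requested; enables the
    #: empirical-rank tail probability for comparison with the fitted CDF
    training_frequencies: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if set(self.alpha) != set(self.beta):
            raise ValueError("alpha and beta must cover the same markers")
        for mid in self.alpha:
            if not (self.alpha[mid] > 0 and self.beta[mid] > 0):
                raise ValueError(f"marker {mid}: Beta parameters must be positive")
        if self.n_controls < 2:
            raise ValueError("a control model needs at least 2 controls")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.alpha)

    def mean(self, marker_id: str) -> float:
        a, b = self.alpha[marker_id], self.beta[marker_id]
        return a / (a + b)


@dataclass(frozen=True)
class MarkerResult:
    """Per-marker scoring detail for one sample."""

    marker_id: str
    wt_frequency: float | None
    p_value: float | None
    included: bool
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class SampleScore:
    """Fisher-combined instability score and threshold calls for one sample."""

    sample_id: str
    marker_results: tuple[MarkerResult, ...]
    k: int
    fisher_statistic: float
    combined_p: float
    score: float
    call_lenient: bool
    call_conservative: bool
    threshold_lenient: float = THRESHOLD_LENIENT
    threshold_conservative: float = THRESHOLD_CONSERVATIVE

    @property
    def degrees_of_freedom(self) -> int:
        return 2 * self.k


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_beta_moments(x: np.ndarray, marker_id: str = "?") -> tuple[float, float]:
    """Closed-form method-of-moments Beta fit.

    With sample mean m and (unbiased) sample variance v, the common factor is
    c = m(1-m)/v - 1, giving alpha = m*c and beta = (1-m)*c. Requires v > 0
    and v < m(1-m) (otherwise no Beta has these moments).
    """
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if v <= 0:
        raise DegenerateVarianceError(
            f"marker {marker_id}: all control frequencies identical (variance 0)"
        )
    c = m * (1.0 - m) / v - 1.0
    if c <= 0:
        raise InvalidMomentsError(
            f"marker {marker_id}: sample variance {v:.3g} too large for a Beta "
            f"with mean {m:.3g}"
        )
    return m * c, (1.0 - m) * c


def _fit_beta_mle(x: np.ndarray, marker_id: str = "?") -> tuple[float, float]:
    a0, b0 = fit_beta_moments(x, marker_id)
    a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0.0, fscale=1.0)
    return float(a), float(b)


def _clamp(x: np.ndarray | float, eps: float) -> np.ndarray | float:
    return np.clip(x, eps, 1.0 - eps)


def fit_control_model(
    control_counts: Mapping[str, Sequence[MarkerCounts]] | pd.DataFrame,
    fit_method: str = "moments",
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON,
    panel_hash: str | None = None,
    keep_training_data: bool = False,
) -> ControlModel:
    """Fit the per-marker Beta model on a control cohort.

    ``control_counts`` is either the mapping produced by
    :func:`msiscope.panel_io.read_counts_table` (markers failing QC in a
    control are dropped for that marker's fit) or a samples x markers
    DataFrame of WT frequencies. Frequencies are clamped into
    ``[clamp_epsilon, 1 - clamp_epsilon]`` before fitting. Each marker needs
    at least two QC-passed controls.
    """
    if fit_method not in ("moments", "mle"):
        raise ValueError(f"unknown fit_method {fit_method!r}")

    if isinstance(control_counts, pd.DataFrame):
        freq_by_marker = {str(mid): control_counts[mid].to_numpy(dtype=float) for mid in control_counts.columns}
        n_controls = len(control_counts)
    else:
        freq_by_marker = {}
        for sample_id, counts in control_counts.items():
            for mc in counts:
                if mc.qc_pass and mc.wt_frequency is not None:
                    freq_by_marker.setdefault(mc.marker_id, []).append(mc.wt_frequency)
        freq_by_marker = {mid: np.asarray(v, dtype=float) for mid, v in freq_by_marker.items()}
        n_controls = len(control_counts)

    fit = fit_beta_moments if fit_method == "moments" else _fit_beta_mle
    alpha: dict[str, float] = {}
    beta: dict[str, float] = {}
    kept: dict[str, np.ndarray] = {}
    for mid, freqs in freq_by_marker.items():
        if len(freqs) < 2:
            raise DegenerateVarianceError(
                f"marker {mid}: {len(freqs)} QC-passed controls (need >= 2)"
            )
        clamped = np.asarray(_clamp(freqs, clamp_epsilon))
        alpha[mid], beta[mid] = fit(clamped, mid)
        if keep_training_data:
            kept[mid] = clamped
    return ControlModel(
        alpha=alpha,
        beta=beta,
        n_controls=n_controls,
        fit_method=fit_method,
        clamp_epsilon=clamp_epsilon,
        panel_hash=panel_hash,
        training_frequencies=kept if keep_training_data else None,
    )


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------


def marker_tail_probability(model: ControlModel, marker_id: str, observed_frequency: float) -> float:
    """P(control WT frequency <= observation) under the marker's fitted Beta.

    Lower observed WT frequency (more instability) gives a smaller p. The
    result is floored at 1e-300 so downstream logs stay finite.
    """
    if marker_id not in model.alpha:
        raise KeyError(f"marker {marker_id} not in control model")
    if not 0.0 <= observed_frequency <= 1.0:
        raise ValueError(f"observed_frequency {observed_frequency} outside [0, 1]")
    x = _clamp(observed_frequency, model.clamp_epsilon)
    p = float(stats.beta.cdf(x, model.alpha[marker_id], model.beta[marker_id]))
    return min(max(p, PROBABILITY_FLOOR), 1.0)


def empirical_tail_probability(model: ControlModel, marker_id: str, observed_frequency: float) -> float:
    """Rank-based alternative to the fitted CDF: (1 + #{controls <= x}) / (n + 1).

    Available only on models fitted with ``keep_training_data=True``; useful
    for checking how much the parametric Beta assumption matters.
    """
    if model.training_frequencies is None:
        raise ValueError("model was fitted without keep_training_data=True")
    train = model.training_frequencies[marker_id]
    x = _clamp(observed_frequency, model.clamp_epsilon)
    return (1.0 + float(np.sum(train <= x))) / (len(train) + 1.0)


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: X^2 = -2 sum(ln p) against chi^2 with 2k df.

    Returns ``(fisher_statistic, combined_p)``. Requires every p in (0, 1]
    and a non-empty list.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise UnscorableSampleError("no p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(statistic, 2 * p.size))
    return statistic, max(combined, PROBABILITY_FLOOR)


def score_from_probability(combined_p: float) -> float:
    """Score = -log10 of the combined probability (0.05 -> 1.30, 0.01 -> 2.00)."""
    if not 0.0 < combined_p <= 1.0:
        raise ValueError(f"combined probability {combined_p} outside (0, 1]")
    return -math.log10(combined_p)


def classify(
    score: float,
    threshold_lenient: float = THRESHOLD_LENIENT,
    threshold_conservative: float = THRESHOLD_CONSERVATIVE,
    inclusive: bool = True,
) -> tuple[bool, bool]:
    """Threshold calls at the 5%- and 1%-equivalent score cut-offs (inclusive)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if inclusive:
        return score >= threshold_lenient, score >= threshold_conservative
    return score > threshold_lenient, score > threshold_conservative


def score_sample(
    model: ControlModel,
    sample_counts: Sequence[MarkerCounts],
    sample_id: str = "sample",
    threshold_lenient: float = THRESHOLD_LENIENT,
    threshold_conservative: float = THRESHOLD_CONSERVATIVE,
    tail_method: str = "beta",
) -> SampleScore:
    """Score one sample end to end.

    Markers are included when they passed coverage QC, have a defined WT
    frequency and are present in the control model; exclusions are recorded
    with a reason and the chi-square degrees of freedom shrink to 2k for the
    k included markers. A sample with zero includable markers is unscorable.
    """
    tail = marker_tail_probability if tail_method == "beta" else empirical_tail_probability
    results: list[MarkerResult] = []
    p_values: list[float] = []
    for mc in sample_counts:
        if mc.marker_id not in model.alpha:
            results.append(MarkerResult(mc.marker_id, mc.wt_frequency, None, False, "not_in_model"))
            continue
        if not mc.qc_pass or mc.wt_frequency is None:
            reason = "no_coverage" if mc.total_count == 0 else "qc_fail"
            results.append(MarkerResult(mc.marker_id, mc.wt_frequency, None, False, reason))
            continue
        p = tail(model, mc.marker_id, mc.wt_frequency)
        results.append(MarkerResult(mc.marker_id, mc.wt_frequency, p, True, None))
        p_values.append(p)

    if not p_values:
        raise UnscorableSampleError(f"sample {sample_id}: no marker passed QC and is modelled")
    statistic, combined = fisher_combine(p_values)
    score = score_from_probability(combined)
    lenient, conservative = classify(score, threshold_lenient, threshold_conservative)
    return SampleScore(
        sample_id=sample_id,
        marker_results=tuple(results),
        k=len(p_values),
        fisher_statistic=statistic,
        combined_p=combined,
        score=score,
        call_lenient=lenient,
        call_conservative=conservative,
        threshold_lenient=threshold_lenient,
        threshold_conservative=threshold_conservative,
    )


def score_frequency_matrix(
    model: ControlModel,
    frequencies: pd.DataFrame,
    threshold_lenient: float = THRESHOLD_LENIENT,
    threshold_conservative: float = THRESHOLD_CONSERVATIVE,
) -> pd.DataFrame:
    """Vectorized scoring of a samples x markers WT-frequency matrix.

    Equivalent to :func:`score_sample` with every marker included (verified
    in the test suite); used for large calibration simulations where per-row
    Python overhead would dominate. Columns must all be modelled markers.
    """
    markers = list(frequencies.columns)
    missing = [m for m in markers if m not in model.alpha]
    if missing:
        raise KeyError(f"markers not in control model: {missing}")
    a = np.array([model.alpha[m] for m in markers])
    b = np.array([model.beta[m] for m in markers])
    x = _clamp(frequencies.to_numpy(dtype=float), model.clamp_epsilon)
    p = np.clip(stats.beta.cdf(x, a, b), PROBABILITY_FLOOR, 1.0)
    statistic = -2.0 * np.log(p).sum(axis=1)
    combined = np.maximum(stats.chi2.sf(statistic, 2 * len(markers)), PROBABILITY_FLOOR)
    score = -np.log10(combined)
    return pd.DataFrame(
        {
            "k": len(markers),
            "fisher_statistic": statistic,
            "combined_p": combined,
            "score": score,
            "call_lenient": score >= threshold_lenient,
            "call_conservative": score >= threshold_conservative,
        },
        index=frequencies.index,
    )


# ---------------------------------------------------------------------------
# model / report IO
# ---------------------------------------------------------------------------

_MODEL_COLUMNS = ["marker_id", "alpha", "beta", "n_controls", "fit_method", "clamp_epsilon"]


def write_control_model(model: ControlModel, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    meta = {
        "n_controls": model.n_controls,
        "fit_method": model.fit_method,
        "clamp_epsilon": model.clamp_epsilon,
    }
    if model.panel_hash:
        meta["panel_hash"] = model.panel_hash
    if metadata:
        meta.update(metadata)
    lines = _format_metadata(meta)
    lines.append("\t".join(_MODEL_COLUMNS))
    for mid in model.marker_ids:
        lines.append(
            "\t".join(
                [
                    mid,
                    repr(model.alpha[mid]),
                    repr(model.beta[mid]),
                    str(model.n_controls),
                    model.fit_method,
                    repr(model.clamp_epsilon),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_control_model(path: str | Path) -> ControlModel:
    from .panel_io import read_table_metadata

    meta = read_table_metadata(path)
    lines = [ln for ln in _read_lines(Path(path)) if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty control model")
    header = lines[0].split("\t")
    missing = set(_MODEL_COLUMNS) - set(header)
    if missing:
        raise ParseError(f"{path}:1: missing columns {sorted(missing)}")
    idx = {c: header.index(c) for c in header}
    alpha: dict[str, float] = {}
    beta: dict[str, float] = {}
    n_controls, fit_method, clamp_epsilon = 2, "moments", DEFAULT_CLAMP_EPSILON
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} columns")
        mid = fields[idx["marker_id"]]
        alpha[mid] = float(fields[idx["alpha"]])
        beta[mid] = float(fields[idx["beta"]])
        n_controls = int(fields[idx["n_controls"]])
        fit_method = fields[idx["fit_method"]]
        clamp_epsilon = float(fields[idx["clamp_epsilon"]])
    return ControlModel(
        alpha=alpha,
        beta=beta,
        n_controls=n_controls,
        fit_method=fit_method,
        clamp_epsilon=clamp_epsilon,
        panel_hash=meta.get("panel_hash"),
    )


def write_score_report(
    scores: Sequence[SampleScore],
    path: str | Path,
    per_marker_path: str | Path | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write the one-row-per-sample score report (and optional long per-marker table).

    The threshold columns are named after the thresholds actually applied
    (``call_1.30`` / ``call_2.00`` at the defaults) so reports are
    self-describing.
    """
    if not scores:
        thr_len, thr_con = THRESHOLD_LENIENT, THRESHOLD_CONSERVATIVE
    else:
        thr_len = scores[0].threshold_lenient
        thr_con = scores[0].threshold_conservative
    columns = [
        "sample_id",
        "k",
        "fisher_statistic",
        "combined_p",
        "score",
        f"call_{thr_len:.2f}",
        f"call_{thr_con:.2f}",
    ]
    meta = {"threshold_lenient": thr_len, "threshold_conservative": thr_con}
    if metadata:
        meta.update(metadata)
    lines = _format_metadata(meta)
    lines.append("\t".join(columns))
    for s in scores:
        lines.append(
            "\t".join(
                [
                    s.sample_id,
                    str(s.k),
                    f"{s.fisher_statistic:.6g}",
                    f"{s.combined_p:.6g}",
                    f"{s.score:.2f}",
                    str(s.call_lenient),
                    str(s.call_conservative),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")

    if per_marker_path is not None:
        long_lines = _format_metadata(meta)
        long_lines.append(
            "\t".join(["sample_id", "marker_id", "wt_frequency", "p_m", "included", "exclusion_reason"])
        )
        for s in scores:
            for r in s.marker_results:
                long_lines.append(
                    "\t".join(
                        [
                            s.sample_id,
                            r.marker_id,
                            "NA" if r.wt_frequency is None else f"{r.wt_frequency:.6g}",
                            "NA" if r.p_value is None else f"{r.p_value:.6g}",
                            str(r.included),
                            r.exclusion_reason or ".",
                        ]
                    )
                )
        Path(per_marker_path).write_text("\n".join(long_lines) + "\n")


def read_score_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
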