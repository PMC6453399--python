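"""Averaging-order-aware trial statistics.

The order in which the trial, session and channel axes of a trial-structured
recording are collapsed decides which axis survives as the *replicate unit*
— the unit whose across-replicate variance a subsequent t-test uses.  Two
canonical orders:

- ``"A-flawed"``: average over trials, then sessions; channels survive.
  The test then treats highly correlated channels as independent replicates,
  so under a pure noise model the variance is grossly understated and
  timepoint-wise t-tests produce a flood of false positives.
- ``"B-correct"``: average over channels, then trials; sessions survive.
  Sessions are (approximately) independent replicates, so the test is
  calibrated.

Both orders produce the same grand-mean curves; only the retained variance
— and hence the inference — differs.  Because channels are correlated,
collapsing them can also dilute a spatially localised effect, so a
per-channel analysis (:func:`channelwise_ttest`, sessions as replicates) is
offered as the recommended alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CONDITIONS, TrialDataset

Axis = Literal["trial", "session", "channel"]
_AXES = ("trial", "session", "channel")

CorrectionLabel = Literal["none", "bonferroni", "bh-fdr"]


@dataclass(frozen=True)
class AveragingSpec:
    """Which two axes to collapse, in order; the third axis survives."""

    order: tuple[Axis, Axis]
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.order) != 2 or len(set(self.order)) != 2:
            raise ValueError("order must name two distinct axes")
        for ax in self.order:
            if ax not in _AXES:
                raise ValueError(f"unknown axis {ax!r}; expected one of {_AXES}")

    @property
    def replicate_unit(self) -> Axis:
        (rem,) = set(_AXES) - set(self.order)
        return rem  # type: ignore[return-value]

    @classmethod
    def from_label(cls, label: str) -> "AveragingSpec":
        if label in ("A", "A-flawed"):
            return METHOD_A
        if label in ("B", "B-correct"):
            return METHOD_B
        raise ValueError(f"unknown method label {label!r}; expected 'A-flawed' or 'B-correct'")


#: trials then sessions collapsed; channels retained as (correlated) replicates
METHOD_A = AveragingSpec(order=("trial", "session"), label="A-flawed")
#: channels then trials collapsed; sessions retained as replicates
METHOD_B = AveragingSpec(order=("channel", "trial"), label="B-correct")


@dataclass
class CollapseResult:
    """Replicate-by-timepoint matrices after a given averaging order."""

    spec: AveragingSpec
    replicates: dict[str, np.ndarray]  # condition -> (n_units, n_timepoints)
    time_axis: np.ndarray

    @property
    def replicate_unit(self) -> Axis:
        return self.spec.replicate_unit

    def grand_mean(self, condition: str) -> np.ndarray:
        return self.replicates[condition].mean(axis=0)

    def replicate_sd(self, condition: str) -> np.ndarray:
        return self.replicates[condition].std(axis=0, ddof=1)


def _check_trials_present(dataset: TrialDataset) -> None:
    for day in dataset.days:
        for sess in day.sessions:
            for cond in CONDITIONS:
                if sess.n_trials(cond) == 0:
                    raise ValueError(
                        f"session {sess.session_id!r} (day {day.day_id!r}) has 0 trials in "
                        f"condition {cond!r}; the averaging orders are undefined there"
                    )


def collapse(dataset: TrialDataset, spec: AveragingSpec) -> CollapseResult:
    """Collapse two axes by unweighted arithmetic means, in the given order.

    Method A (``order=("trial", "session")``): per-session trial means, then
    the mean over sessions; rows of the result are channels.  Method B
    (``order=("channel", "trial")``): per-trial channel means, then
    per-session trial means; rows are sessions.

    Collapsing ``"session"`` before ``"trial"`` is only defined when every
    session has the same per-condition trial count.
    """
    _check_trials_present(dataset)
    out: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        # per-session stack of (trial, channel, time) arrays; axes collapse in order
        per_session = [s.trials(cond) for _, s in dataset.iter_sessions()]
        axis_names = ["trial", "channel"]  # axes inside each session array (time is last)
        for ax in spec.order:
            if ax == "session":
                if len({a.shape for a in per_session}) > 1:
                    raise ValueError(
                        "collapsing 'session' before 'trial' requires equal per-session "
                        "trial counts"
                    )
                per_session = [np.mean(np.stack(per_session, axis=0), axis=0)]
            else:
                idx = axis_names.index(ax)
                per_session = [a.mean(axis=idx) for a in per_session]
                axis_names.pop(idx)
        if spec.replicate_unit == "session":
            # each session reduced to a (time,) curve
            rows = np.stack([a.reshape(-1) for a in per_session], axis=0)
        else:
            (arr,) = per_session
            rows = arr  # (units, time): channels or trials
        out[cond] = rows
    return CollapseResult(spec=spec, replicates=out, time_axis=dataset.time_axis)


@dataclass
class TestCurve:
    """Timepoint-wise two-sample t statistics with significance mask."""

    t: np.ndarray
    p: np.ndarray
    df: np.ndarray
    alpha: float
    correction: CorrectionLabel
    mask: np.ndarray
    replicate_unit: str
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    p_adjusted: np.ndarray | None = None

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


def _adjust(p: np.ndarray, alpha: float, correction: CorrectionLabel) -> tuple[np.ndarray, np.ndarray]:
    """Return (mask, adjusted p) for a flat vector of p-values."""
    if correction == "none":
        return p < alpha, p
    method = {"bonferroni": "bonferroni", "bh-fdr": "fdr_bh"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r}; expected none, bonferroni or bh-fdr")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    return reject, p_adj


def _ttest_matrices(
    yes: np.ndarray, no: np.ndarray, paired: bool, equal_var: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise t-tests with explicit zero-variance handling.

    Returns (t, p, df, degenerate) where *degenerate* marks timepoints with
    zero variance but unequal means (p forced to 0, t to signed inf).
    """
    if yes.shape[0] < 2 or no.shape[0] < 2:
        raise ValueError("need at least 2 replicate units per condition for a t-test")
    if paired:
        if yes.shape[0] != no.shape[0]:
            raise ValueError("paired test requires matched replicate counts")
        res = stats.ttest_rel(yes, no, axis=0)
        df = np.full(yes.shape[1], float(yes.shape[0] - 1))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(yes, no, axis=0, equal_var=equal_var)
        df = np.broadcast_to(np.asarray(res.df, dtype=float), (yes.shape[1],)).copy()
    t = np.asarray(res.statistic, dtype=float).copy()
    p = np.asarray(res.pvalue, dtype=float).copy()
    diff = yes.mean(axis=0) - no.mean(axis=0)
    novar = np.nan_to_num(yes.var(axis=0) + no.var(axis=0), nan=0.0) == 0.0
    ties = novar & (diff == 0.0)
    t[ties], p[ties] = 0.0, 1.0
    degen = novar & (diff != 0.0)
    if degen.any():
        t[degen] = np.sign(diff[degen]) * np.inf
        p[degen] = 0.0
        warnings.warn(
            f"{int(degen.sum())} timepoint(s) have zero variance with unequal means; "
            "p set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return t, p, df, degen


def timepoint_ttest(
    result: CollapseResult,
    paired: bool = False,
    alpha: float = 0.05,
    correction: CorrectionLabel = "none",
    equal_var: bool = True,
) -> TestCurve:
    """Two-sample t-test between yes- and no-replicates at every timepoint.

    The default is the unpaired pooled-variance Student test; ``paired`` and
    ``equal_var=False`` (Welch) variants cover the ambiguity about what the
    original analyses used.  Zero pooled variance with equal means gives
    t = 0, p = 1; zero variance with unequal means gives p = 0 and a
    degenerate-variance warning.
    """
    t, p, df, degen = _ttest_matrices(result.replicates["yes"], result.replicates["no"], paired, equal_var)
    mask, p_adj = _adjust(p, alpha, correction)
    return TestCurve(
        t=t, p=p, df=df, alpha=alpha, correction=correction, mask=mask,
        replicate_unit=result.replicate_unit, degenerate=degen, p_adjusted=p_adj,
    )


def channelwise_ttest(
    dataset: TrialDataset,
    alpha: float = 0.05,
    correction: CorrectionLabel = "none",
    paired: bool = False,
    equal_var: bool = True,
) -> list[TestCurve]:
    """Per-channel session-replicate t-tests (the recommended analysis).

    For each channel separately: trials are averaged within each session
    (keeping only that channel), sessions become the replicates, and a
    timepoint-wise t-test is run.  When a correction is requested it is
    applied jointly across channels x timepoints.
    """
    _check_trials_present(dataset)
    n_sessions = sum(1 for _ in dataset.iter_sessions())
    if n_sessions < 2:
        raise ValueError("channelwise analysis needs at least 2 sessions")
    sess_means = {
        cond: np.stack([s.trials(cond).mean(axis=0) for _, s in dataset.iter_sessions()])
        for cond in CONDITIONS
    }  # (session, channel, time)
    raw = []
    for c in range(dataset.n_channels):
        t, p, df, degen = _ttest_matrices(
            sess_means["yes"][:, c, :], sess_means["no"][:, c, :], paired, equal_var
        )
        raw.append((t, p, df, degen))
    all_p = np.concatenate([r[1] for r in raw])
    mask_flat, padj_flat = _adjust(all_p, alpha, correction)
    n_tp = dataset.n_timepoints
    curves = []
    for c, (t, p, df, degen) in enumerate(raw):
        sl = slice(c * n_tp, (c + 1) * n_tp)
        curves.append(
            TestCurve(
                t=t, p=p, df=df, alpha=alpha, correction=correction,
                mask=mask_flat[sl], replicate_unit="session", degenerate=degen,
                p_adjusted=padj_flat[sl],
            )
        )
    return curves


# ---------------------------------------------------------------------------
# side-by-side method comparison (Model/Results interface)
# ---------------------------------------------------------------------------

METHOD_LABELS = ("A-flawed", "B-correct")


@dataclass
class MethodComparisonResults:
    """Side-by-side collapse + test results for both averaging orders."""

    collapsed: dict[str, CollapseResult]
    tests: dict[str, TestCurve]
    alpha: float
    correction: CorrectionLabel
    time_axis: np.ndarray

    @property
    def n_significant(self) -> dict[str, int]:
        return {m: self.tests[m].n_significant for m in METHOD_LABELS}

    def summary(self) -> str:
        lines = [
            "Averaging-order comparison",
            "==========================",
            f"alpha = {self.alpha:g}, correction = {self.correction}",
        ]
        for m in METHOD_LABELS:
            tc = self.tests[m]
            lines.append(
                f"{m:>10}: replicate unit = {tc.replicate_unit:8s} "
                f"df = {tc.df[0]:.0f}  significant timepoints = "
                f"{tc.n_significant}/{tc.mask.size}"
            )
        return "\n".join(lines)

    def plot(self, path=None):
        from .plotting import render_comparison_figure

        return render_comparison_figure(self, path)

    def to_dict(self) -> dict:
        out: dict = {
            "schema_version": 1,
            "alpha": self.alpha,
            "correction": self.correction,
            "methods": {},
        }
        for m in METHOD_LABELS:
            tc, cr = self.tests[m], self.collapsed[m]
            out["methods"][m] = {
                "replicate_unit": tc.replicate_unit,
                "n_significant": tc.n_significant,
                "n_timepoints": int(tc.mask.size),
                "df": tc.df.tolist(),
                "t": tc.t.tolist(),
                "p": tc.p.tolist(),
                "mask": tc.mask.astype(bool).tolist(),
                "grand_mean": {c: cr.grand_mean(c).tolist() for c in CONDITIONS},
                "replicate_sd": {c: cr.replicate_sd(c).tolist() for c in CONDITIONS},
            }
        out["time_axis_s"] = self.time_axis.tolist()
        return out


def compare_methods(
    dataset: TrialDataset,
    alpha: float = 0.05,
    correction: CorrectionLabel = "none",
    paired: bool = False,
) -> MethodComparisonResults:
    """Run both averaging orders and their t-tests on one dataset."""
    collapsed = {"A-flawed": collapse(dataset, METHOD_A), "B-correct": collapse(dataset, METHOD_B)}
    tests = {
        m: timepoint_ttest(collapsed[m], paired=paired, alpha=alpha, correction=correction)
        for m in METHOD_LABELS
    }
    return MethodComparisonResults(
        collapsed=collapsed, tests=tests, alpha=alpha, correction=correction,
        time_axis=dataset.time_axis,
    )


class AveragingComparison:
    """Model-style front end: compare both averaging orders on a dataset.

    >>> res = AveragingComparison(dataset, alpha=0.05).fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        dataset: TrialDataset,
        alpha: float = 0.05,
        correction: CorrectionLabel = "none",
        paired: bool = False,
    ) -> None:
        self.dataset = dataset
        self.alpha = alpha
        self.correction = correction
        self.paired = paired

    def fit(self) -> MethodComparisonResults:
        return compare_methods(
            self.dataset, alpha=self.alpha, correction=self.correction, paired=self.paired
        )
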